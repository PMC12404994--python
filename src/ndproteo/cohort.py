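"""Synthetic multi-site plasma-proteomics cohorts with known ground truth.

The generator emulates the statistical structure the downstream stages
assume: ~16 contributor sites with additive site intercepts, one sodium
citrate site among EDTA sites, planted per-disease effects on a fraction of
aptamers (optionally shared across disease pairs with a controllable
cross-disease effect-size correlation), age and sex covariate slopes,
missing-completely-at-random entries, heavy-tailed outlier spikes, and
signed Boolean regulatory networks whose fixed points define Booleanized
disease states. The returned :class:`CohortTruth` carries everything an
acceptance test needs as an oracle.

Abundance model (log10 scale, per sample i / aptamer j)::

    log10(RFU_ij) = mu_j + site_offset[site_i] + age_c_i * a_j
                    + sex_i * s_j + beta[d_i, j] * sigma_j + eps_ij

with ``mu_j ~ U[2, 4]``, noise s.d. ``sigma_j ~ U[0.1, 0.3]`` (mimicking the
RFU dynamic range of an aptamer panel) and planted effects ``beta`` in
z-score units, so the downstream covariate-adjusted effect size on
z-score-normalized data estimates ``beta`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .containers import (AbundanceMatrix, SpecificationError, PipelineError,
                         validate_fraction, validate_positive, rng_for,
                         SCALE_RFU)
from .network import (SignedBooleanNetwork, simulate_dynamics, ACTIVATE,
                      INHIBIT)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort. Identical spec + seed gives
    bit-identical output."""

    n_per_group: dict = field(default_factory=lambda: {
        "control": 300, "AD": 150, "PD": 100, "FTD": 60})
    n_sites: int = 16
    citrate_sites: tuple | None = None   # None: last site, if >= 2 sites
    n_aptamers: int = 1000
    frac_signal: float = 0.1
    effect_scale: float = 0.5
    shared_block_spec: dict = field(default_factory=dict)
    age_effect_sd: float = 0.002
    sex_effect_sd: float = 0.02
    site_offset_sd: float = 0.1
    missing_rate: float = 0.05
    outlier_rate: float = 0.002
    outlier_magnitude: float = 3.0
    n_nonhuman: int = 0
    effect_distribution: str = "normal"   # "normal" or "fixed" (+effect_scale)
    seed: int = 0

    @property
    def site_ids(self) -> list:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    @property
    def citrate_site_ids(self) -> tuple:
        if self.citrate_sites is None:
            return (self.site_ids[-1],) if self.n_sites >= 2 else ()
        return tuple(self.citrate_sites)

    @property
    def diseases(self) -> list:
        return [g for g in self.n_per_group if g != "control"]

    def validate(self) -> None:
        for name in ("frac_signal", "missing_rate", "outlier_rate"):
            validate_fraction(getattr(self, name), name)
        for name in ("n_sites", "n_aptamers"):
            validate_positive(getattr(self, name), name)
        for group, n in self.n_per_group.items():
            if n <= 0:
                raise SpecificationError(
                    f"n_per_group[{group!r}] must be positive, got {n}")
        if "control" not in self.n_per_group:
            raise SpecificationError("n_per_group must include 'control'")
        unknown = set(self.citrate_site_ids) - set(self.site_ids)
        if unknown:
            raise SpecificationError(
                f"citrate_sites not among site ids: {sorted(unknown)}")
        for pair, block in self.shared_block_spec.items():
            if len(pair) != 2 or any(d not in self.diseases for d in pair):
                raise SpecificationError(
                    f"shared_block_spec pair {pair!r} not a disease pair")
            validate_fraction(block.get("frac_shared", 0.0),
                              f"shared_block_spec[{pair}].frac_shared")
            validate_fraction(block.get("r2_target", 0.0),
                              f"shared_block_spec[{pair}].r2_target")
        if self.outlier_magnitude < 0 or self.site_offset_sd < 0:
            raise SpecificationError(
                "outlier_magnitude and site_offset_sd must be >= 0")
        if self.effect_distribution not in ("normal", "fixed"):
            raise SpecificationError(
                "effect_distribution must be 'normal' or 'fixed'")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort (the acceptance-test oracle)."""

    true_beta: pd.DataFrame          # aptamer x disease, z-score units
    true_site_offsets: dict          # site id -> log10 offset
    outlier_positions: list          # (sample_id, aptamer_id) tuples
    missing_positions: list
    true_network: SignedBooleanNetwork | None = None
    age_slopes: pd.Series | None = None
    sex_slopes: pd.Series | None = None
    noise_sd: pd.Series | None = None


def _plant_effects(spec: CohortSpec, aptamer_ids, rng) -> pd.DataFrame:
    """Planted effect matrix. Shared blocks draw a latent common effect and
    disease-specific components with loading a = r2_target**0.25 per axis so
    that corr(beta_x, beta_y) = sqrt(r2_target), i.e. the squared Pearson
    correlation of the planted effects hits r2_target in expectation."""
    m = len(aptamer_ids)
    diseases = spec.diseases
    beta = pd.DataFrame(0.0, index=aptamer_ids, columns=diseases)
    n_signal = int(round(spec.frac_signal * m))
    if n_signal == 0 or not diseases:
        return beta

    available = np.arange(m)
    signal_sets: dict[str, np.ndarray] = {}
    # shared blocks first (pairwise, non-overlapping across pairs)
    used = np.zeros(m, dtype=bool)
    for (d1, d2), block in spec.shared_block_spec.items():
        n_shared = int(round(block.get("frac_shared", 0.0) * n_signal))
        if n_shared == 0:
            continue
        free = available[~used]
        idx = rng.choice(free, size=min(n_shared, len(free)), replace=False)
        used[idx] = True
        a = block.get("r2_target", 0.0) ** 0.25
        b = np.sqrt(max(1.0 - a * a, 0.0))
        latent = rng.standard_normal(len(idx))
        for d in (d1, d2):
            own = rng.standard_normal(len(idx))
            beta.iloc[idx, beta.columns.get_loc(d)] = (
                spec.effect_scale * (a * latent + b * own))
            # a fixed-effect cohort still honors the shared-block draw
            if spec.effect_distribution == "fixed":
                beta.iloc[idx, beta.columns.get_loc(d)] = spec.effect_scale
            signal_sets.setdefault(d, np.array([], dtype=int))
            signal_sets[d] = np.union1d(signal_sets[d], idx)
    # independent disease-specific signal to top each disease up to n_signal
    for d in diseases:
        have = signal_sets.get(d, np.array([], dtype=int))
        n_more = n_signal - len(have)
        if n_more > 0:
            free = available[~used]
            idx = rng.choice(free, size=min(n_more, len(free)), replace=False)
            used[idx] = True
            if spec.effect_distribution == "fixed":
                draws = np.full(len(idx), spec.effect_scale)
            else:
                draws = spec.effect_scale * rng.standard_normal(len(idx))
            beta.iloc[idx, beta.columns.get_loc(d)] = draws
    return beta


def generate_cohort(spec: CohortSpec):
    """Generate one cohort.

    Returns ``(matrix, metadata, annotation, truth)``; ``matrix`` is on the
    RFU scale with missingness and outliers already injected.
    """
    spec.validate()
    n_total = sum(spec.n_per_group.values())
    aptamer_ids = [f"APT{j + 1:05d}" for j in range(spec.n_aptamers)]

    rng_meta = rng_for(spec.seed, "metadata")
    rng_mat = rng_for(spec.seed, "matrix")
    rng_eff = rng_for(spec.seed, "effects")
    rng_miss = rng_for(spec.seed, "missingness")
    rng_out = rng_for(spec.seed, "outliers")

    # --- sample metadata -------------------------------------------------
    sample_ids = [f"SAMP{i + 1:05d}" for i in range(n_total)]
    diagnosis = np.repeat(list(spec.n_per_group),
                          list(spec.n_per_group.values()))
    sites = np.array(spec.site_ids)[rng_meta.integers(0, spec.n_sites,
                                                      size=n_total)]
    age = rng_meta.uniform(55.0, 85.0, size=n_total).round(1)
    sex = np.where(rng_meta.random(n_total) < 0.5, "F", "M")
    is_control = diagnosis == "control"
    cdr = np.where(is_control, 0.0,
                   rng_meta.choice([0.5, 1.0, 2.0], size=n_total))
    mmse = np.where(is_control, rng_meta.integers(24, 31, size=n_total),
                    rng_meta.integers(10, 27, size=n_total))
    citrate_ids = list(spec.citrate_site_ids)
    anticoagulant = np.where(np.isin(sites, citrate_ids), "citrate", "EDTA")
    metadata = pd.DataFrame({
        "sample_id": sample_ids, "diagnosis": diagnosis, "age": age,
        "sex": sex, "site": sites, "anticoagulant": anticoagulant,
        "CDR": cdr, "MMSE": mmse,
    }).set_index("sample_id", drop=False)

    # --- planted structure ------------------------------------------------
    mu = rng_mat.uniform(2.0, 4.0, size=spec.n_aptamers)
    sigma = rng_mat.uniform(0.1, 0.3, size=spec.n_aptamers)
    site_offsets = {s: o for s, o in zip(
        spec.site_ids,
        rng_mat.normal(0.0, spec.site_offset_sd, size=spec.n_sites))}
    age_slopes = rng_eff.normal(0.0, spec.age_effect_sd, size=spec.n_aptamers)
    sex_slopes = rng_eff.normal(0.0, spec.sex_effect_sd, size=spec.n_aptamers)
    beta = _plant_effects(spec, aptamer_ids, rng_eff)

    # --- log10 abundance ---------------------------------------------------
    log_vals = mu[None, :] + rng_mat.normal(
        0.0, 1.0, size=(n_total, spec.n_aptamers)) * sigma[None, :]
    log_vals += np.array([site_offsets[s] for s in sites])[:, None]
    age_c = age - age.mean()
    log_vals += age_c[:, None] * age_slopes[None, :]
    log_vals += (sex == "M").astype(float)[:, None] * sex_slopes[None, :]
    for d in spec.diseases:
        rows = diagnosis == d
        log_vals[rows, :] += (beta[d].to_numpy() * sigma)[None, :]

    # --- outliers: planted at +/- outlier_magnitude x IQR beyond the hinge,
    # with fences per processing group so the QC rule provably catches them
    groups = np.where(anticoagulant == "citrate",
                      np.char.add("citrate_", sites), "EDTA")
    outlier_positions = []
    if spec.outlier_rate > 0:
        flags = rng_out.random((n_total, spec.n_aptamers)) < spec.outlier_rate
        signs = np.where(rng_out.random((n_total, spec.n_aptamers)) < 0.5,
                         1.0, -1.0)
        for grp in np.unique(groups):
            rows = np.flatnonzero(groups == grp)
            if len(rows) < 4:
                continue
            q1, q3 = np.quantile(log_vals[rows, :], [0.25, 0.75], axis=0)
            iqr = q3 - q1
            for r in rows:
                for c in np.flatnonzero(flags[r]):
                    if signs[r, c] > 0:
                        log_vals[r, c] = q3[c] + spec.outlier_magnitude * iqr[c]
                    else:
                        log_vals[r, c] = q1[c] - spec.outlier_magnitude * iqr[c]
                    outlier_positions.append((sample_ids[r], aptamer_ids[c]))

    rfu = np.power(10.0, log_vals)

    # --- MCAR missingness (never on an injected outlier cell) --------------
    missing_positions = []
    if spec.missing_rate > 0:
        miss = rng_miss.random((n_total, spec.n_aptamers)) < spec.missing_rate
        smp_idx = {s: i for i, s in enumerate(sample_ids)}
        apt_idx = {a: j for j, a in enumerate(aptamer_ids)}
        for smp, apt in outlier_positions:
            miss[smp_idx[smp], apt_idx[apt]] = False
        rfu[miss] = np.nan
        rr, cc = np.nonzero(miss)
        missing_positions = [(sample_ids[r], aptamer_ids[c])
                             for r, c in zip(rr, cc)]

    # --- non-human spike-in aptamers for QC fixtures -----------------------
    annotation = pd.DataFrame({
        "aptamer_id": aptamer_ids,
        "protein": [f"PROT{j + 1:05d}" for j in range(spec.n_aptamers)],
        "organism": "human",
    })
    if spec.n_nonhuman > 0:
        extra_ids = [f"APTNH{j + 1:03d}" for j in range(spec.n_nonhuman)]
        extra_vals = np.power(10.0, rng_mat.normal(
            3.0, 0.2, size=(n_total, spec.n_nonhuman)))
        rfu = np.concatenate([rfu, extra_vals], axis=1)
        annotation = pd.concat([annotation, pd.DataFrame({
            "aptamer_id": extra_ids,
            "protein": [f"NHPROT{j + 1:03d}" for j in range(spec.n_nonhuman)],
            "organism": "mouse"})], ignore_index=True)
        aptamer_ids = aptamer_ids + extra_ids
        beta = beta.reindex(aptamer_ids, fill_value=0.0)

    values = pd.DataFrame(rfu, index=pd.Index(sample_ids, name="sample_id"),
                          columns=aptamer_ids)
    matrix = AbundanceMatrix(values, scale=SCALE_RFU,
                             groups=pd.Series(groups, index=values.index))
    truth = CohortTruth(
        true_beta=beta, true_site_offsets=site_offsets,
        outlier_positions=outlier_positions,
        missing_positions=missing_positions,
        age_slopes=pd.Series(age_slopes, index=values.columns[:len(age_slopes)]),
        sex_slopes=pd.Series(sex_slopes, index=values.columns[:len(sex_slopes)]),
        noise_sd=pd.Series(sigma, index=values.columns[:len(sigma)]),
    )
    return matrix, metadata, annotation, truth


# ---------------------------------------------------------------------------
# ground-truth regulatory networks
# ---------------------------------------------------------------------------

def generate_truth_network(n_nodes: int, edge_density: float,
                           frac_inhibitory: float = 0.3, seed: int = 0,
                           max_retries: int = 50,
                           source_high_prob: float = 0.7):
    """Random signed digraph plus a node-state vector that is a fixed point
    of the inhibitor-dominant update rule.

    Source nodes (in-degree 0) are clamped — set to 1 with probability
    ``source_high_prob`` — and states propagate downstream until a fixed
    point; runs ending in a limit cycle are retried with fresh topology.

    Returns ``(network, string_table)`` where ``string_table`` is the
    corresponding undirected, unsigned STRING-like edge frame with combined
    scores >= 0.7.
    """
    validate_fraction(edge_density, "edge_density")
    validate_fraction(frac_inhibitory, "frac_inhibitory")
    if n_nodes < 3:
        raise SpecificationError("need at least 3 nodes")
    for attempt in range(max_retries):
        rng = rng_for(seed, f"truthnet-{attempt}")
        nodes = [f"P{i + 1:02d}" for i in range(n_nodes)]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if i != j and rng.random() < edge_density / 2.0:
                    if not g.has_edge(v, u):  # keep at most one orientation
                        sign = (INHIBIT if rng.random() < frac_inhibitory
                                else ACTIVATE)
                        g.add_edge(u, v, sign=sign)
        comp = max(nx.connected_components(g.to_undirected()),
                   key=len, default=set())
        if len(comp) < 3:
            continue
        g = g.subgraph(comp).copy()
        sources = [v for v in g.nodes() if g.in_degree(v) == 0]
        if not sources:
            sources = [sorted(g.nodes())[0]]
        clamp = {v: int(rng.random() < source_high_prob) for v in sources}
        init = {v: int(rng.random() < 0.5) for v in g.nodes()}
        net = SignedBooleanNetwork(g, {v: init.get(v, 0) for v in g.nodes()},
                                   clamped=set(clamp))
        res = simulate_dynamics(net, init, clamped_nodes=clamp)
        if res.reached_cycle:
            continue
        net = SignedBooleanNetwork(g, res.final_states, clamped=set(clamp))
        # verify the emitted state really is a fixed point
        check = simulate_dynamics(net, res.final_states, clamped_nodes=clamp)
        if check.n_steps > 1 or check.final_states != res.final_states:
            continue
        rows = []
        for u, v in g.edges():
            a, b = sorted((u, v))
            rows.append({"protein1": a, "protein2": b,
                         "experimental": round(float(rng.uniform(0.4, 1.0)), 3),
                         "database": round(float(rng.uniform(0.0, 1.0)), 3),
                         "combined_score": int(rng.uniform(700, 1000))})
        table = pd.DataFrame(rows).drop_duplicates(["protein1", "protein2"])
        return net, table
    raise PipelineError("no fixed-point network found within retry budget")


# ---------------------------------------------------------------------------
# enrichment fixtures: cell-type reference + gene-set database
# ---------------------------------------------------------------------------

def generate_references(n_genes: int, n_celltypes: int, frac_specific: float,
                        n_sets: int, set_size: int, seed: int = 0,
                        specificity_ratio: float = 2.0):
    """Cell-type reference expression table and GMT-style gene sets.

    Planted cell-type-specific genes satisfy the 1.5x specificity rule by
    construction (their top cell type exceeds every other by
    ``specificity_ratio``). The first gene set (``SET001``) doubles as the
    planted "enriched" set for a designated query.

    Returns ``(reference, gene_sets, truth)`` where ``truth`` maps planted
    specific genes to their cell type and names the planted enriched set.
    """
    validate_fraction(frac_specific, "frac_specific")
    if set_size > n_genes:
        raise SpecificationError("set_size cannot exceed n_genes")
    if n_celltypes < 2:
        raise SpecificationError("need at least 2 cell types")
    if specificity_ratio < 1.5:
        raise SpecificationError("specificity_ratio must be >= 1.5")
    rng = rng_for(seed, "references")
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    celltypes = [f"CT{i + 1:02d}" for i in range(n_celltypes)]
    # background expression spans less than a 1.5-fold range so that
    # non-specific genes fail the specificity rule by construction
    base = rng.uniform(1.0, 1.4, size=(n_genes, n_celltypes))
    n_specific = int(round(frac_specific * n_genes))
    specific_idx = rng.choice(n_genes, size=n_specific, replace=False)
    assigned_ct = rng.integers(0, n_celltypes, size=n_specific)
    planted = {}
    for gi, ci in zip(specific_idx, assigned_ct):
        base[gi, ci] = specificity_ratio * base[gi].max() * 1.01
        planted[genes[gi]] = celltypes[ci]
    reference = pd.DataFrame(base, index=genes, columns=celltypes)
    sets = {}
    for k in range(n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets[f"SET{k + 1:03d}"] = sorted(members)
    truth = {"specific_genes": planted, "enriched_set": "SET001"}
    return reference, sets, truth
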