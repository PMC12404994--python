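"""End-to-end orchestration of the synthetic-cohort analysis pipeline.

``run_pipeline`` executes simulate -> qc -> assoc -> compare -> meta ->
enrich -> network -> panel with one global seed fanned out per stage, and
records a provenance manifest (input file hashes, parameters, seeds). A
rerun against a directory whose recorded inputs have changed refuses with a
provenance error.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ndio
from .containers import PipelineError, SpecificationError, derive_seed
from .cohort import (CohortSpec, generate_cohort, generate_truth_network,
                     generate_references)
from .qc import QCParams, run_qc
from .association import fit_associations, tertile_odds_ratios
from .crossdisease import overlap_sets, pairwise_comparisons
from .sitemeta import by_site_meta
from .enrichment import hypergeom_enrich, map_aptamers_to_genes
from .network import GAParams, build_graph, reconstruct_boolean, \
    rank_perturbagens
from .panels import PanelParams, prune_correlated, stability_select, \
    evaluate_panel

_KNOWN_KEYS = {
    "seed", "out_dir", "cohort", "qc", "covariates", "q_threshold",
    "min_string_score", "ga", "panel", "diseases", "enrichment",
}


def _apply_defaults(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise SpecificationError(f"unknown config keys: {sorted(unknown)}")
    config = dict(config)
    config.setdefault("seed", 0)
    config.setdefault("q_threshold", 0.05)
    config.setdefault("min_string_score", 0.7)
    config.setdefault("covariates", ["age", "sex", "PC1", "PC2"])
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    return _apply_defaults(config)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_manifest(out: Path) -> None:
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        return
    manifest = json.loads(manifest_path.read_text())
    for stage in manifest.get("stages", []):
        for rel, digest in stage.get("inputs", {}).items():
            p = out / rel
            if p.exists() and _sha256(p) != digest:
                raise PipelineError(
                    f"provenance error: {rel} changed since it was recorded "
                    f"by stage {stage['name']!r}")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run every stage on a freshly simulated cohort; returns the manifest."""
    config = _apply_defaults(config)
    out = Path(out_dir or config.get("out_dir", "ndproteo_run"))
    out.mkdir(parents=True, exist_ok=True)
    _check_manifest(out)
    seed = int(config.get("seed", 0))
    stages = []

    def record(name, inputs=(), params=None):
        stages.append({
            "name": name,
            "seed": derive_seed(seed, name),
            "inputs": {str(rel): _sha256(out / rel) for rel in inputs},
            "params": params or {},
        })

    # --- simulate ---------------------------------------------------------
    cohort_cfg = dict(config.get("cohort", {}))
    spec = CohortSpec(**cohort_cfg, seed=derive_seed(seed, "simulate"))
    matrix, metadata, annotation, truth = generate_cohort(spec)
    ndio.write_abundance_tsv(matrix, out / "abundance.tsv")
    ndio.write_table_tsv(metadata.reset_index(drop=True), out / "metadata.tsv")
    ndio.write_table_tsv(annotation, out / "annotation.tsv")
    ndio.write_truth_json(truth, out / "truth.json")
    record("simulate", ["abundance.tsv", "metadata.tsv", "annotation.tsv"],
           {"n_samples": matrix.n_samples, "n_aptamers": matrix.n_aptamers})

    # --- qc ---------------------------------------------------------------
    qc_params = QCParams(**config.get("qc", {}), seed=derive_seed(seed, "qc"))
    zmat, pcs, report = run_qc(matrix, annotation, qc_params)
    metadata = metadata.loc[zmat.sample_ids]
    ndio.write_abundance_tsv(zmat, out / "zscored.tsv")
    ndio.write_table_tsv(pcs.reset_index(), out / "pcs.tsv")
    report.to_json(out / "qc_report.json")
    record("qc", ["zscored.tsv", "pcs.tsv"], {"final_dims": report.final_dims})

    # --- associations per disease ------------------------------------------
    covariates = config["covariates"]
    diseases = config.get("diseases") or spec.diseases
    tables = {}
    for disease in diseases:
        tab = fit_associations(zmat, metadata, covariates, disease,
                               covariate_table=pcs)
        tables[disease] = tab
        ndio.write_table_tsv(tab, out / f"assoc_{disease}.tsv")
        sig = tab.loc[tab["q"] < config["q_threshold"], "aptamer"]
        if len(sig) >= 2:
            or_tab, or_summary = tertile_odds_ratios(
                zmat, metadata, covariates, disease,
                aptamer_subset=list(sig)[:200], covariate_table=pcs)
            ndio.write_table_tsv(or_tab, out / f"tertile_or_{disease}.tsv")
            (out / f"or_summary_{disease}.json").write_text(
                json.dumps(or_summary))
    record("assoc", [f"assoc_{d}.tsv" for d in diseases],
           {"covariates": covariates})

    # --- cross-disease comparison ------------------------------------------
    overlaps = overlap_sets(tables, config["q_threshold"])
    (out / "overlaps.json").write_text(json.dumps(
        {"counts": {"+".join(sorted(k)): v
                    for k, v in overlaps["counts"].items()},
         "union_size": overlaps["union_size"]}))
    comparisons = {}
    if len(tables) >= 2:
        try:
            comparisons = pairwise_comparisons(tables)
            summary = {f"{a}-{b}": {"r2": c.r2, "slope": c.slope,
                                    "direction": c.direction_summary}
                       for (a, b), c in comparisons.items()}
            (out / "comparisons.json").write_text(json.dumps(summary))
        except Exception:          # too few significant aptamers
            comparisons = {}
    record("compare", ["overlaps.json"])

    # --- by-site meta-analysis ---------------------------------------------
    meta_done = []
    for disease in diseases:
        try:
            meta_tab, _ = by_site_meta(zmat, metadata, covariates, disease,
                                       covariate_table=pcs)
            ndio.write_table_tsv(meta_tab, out / f"meta_{disease}.tsv")
            meta_done.append(disease)
        except Exception:
            continue
    record("meta", [f"meta_{d}.tsv" for d in meta_done])

    # --- enrichment on a synthetic gene-set DB ------------------------------
    enrich_cfg = config.get("enrichment", {})
    n_genes = int(enrich_cfg.get("n_genes", 400))
    _, gene_sets, _ = generate_references(
        n_genes=n_genes, n_celltypes=5, frac_specific=0.3, n_sets=20,
        set_size=min(25, n_genes), seed=derive_seed(seed, "enrich"))
    ndio.write_gmt(gene_sets, out / "gene_sets.gmt")
    enrich_written = False
    for disease, tab in tables.items():
        sig = tab.loc[tab["q"] < config["q_threshold"], "aptamer"]
        genes = map_aptamers_to_genes(sig, annotation)
        # annotation proteins are synthetic ids; map onto the gene universe
        universe = sorted(set().union(*gene_sets.values()))
        import zlib
        query = [universe[zlib.crc32(g.encode()) % len(universe)]
                 for g in genes]
        if query:
            enr = hypergeom_enrich(query, gene_sets, universe=universe)
            ndio.write_table_tsv(enr, out / f"enrich_{disease}.tsv")
            enrich_written = True
    record("enrich", ["gene_sets.gmt"] if enrich_written else [])

    # --- regulatory network -------------------------------------------------
    net_seed = derive_seed(seed, "network")
    truth_net, string_table = generate_truth_network(
        n_nodes=12, edge_density=0.3, seed=net_seed)
    ndio.write_interactions_tsv(string_table, out / "interactions.tsv")
    ga = GAParams(**config.get("ga", {}), seed=net_seed)
    skeleton = truth_net.graph.to_undirected()
    recon, consistency, details = reconstruct_boolean(
        skeleton, truth_net.states, ga)
    ranks = rank_perturbagens(recon)
    ndio.write_table_tsv(recon.to_sif_frame(), out / "network_sif.tsv")
    ndio.write_table_tsv(ranks.drop(columns=["flipped"]),
                         out / "perturbagen_ranks.tsv")
    record("network", ["interactions.tsv", "network_sif.tsv"],
           {"consistency": consistency, "fitness": details["fitness"]})

    # --- biomarker panel ----------------------------------------------------
    panel_cfg = dict(config.get("panel", {}))
    panel_done = []
    for disease in diseases:
        panel_params = PanelParams(**panel_cfg,
                                   seed=derive_seed(seed, f"panel-{disease}"))
        tab = tables[disease].set_index("aptamer")
        sig = tab.index[tab["q"] < config["q_threshold"]].tolist()
        if len(sig) < panel_params.panel_size:
            continue
        mask = metadata["diagnosis"].isin([disease, "control"])
        sub_vals = zmat.values.loc[metadata.index[mask]]
        y = metadata.loc[mask, "diagnosis"].eq(disease).to_numpy(int)
        kept = prune_correlated(sub_vals, sig, tab["q"],
                                panel_params.prune_r2)
        if len(kept) < panel_params.panel_size or y.sum() < 10:
            continue
        try:
            freqs, panel, _ = stability_select(sub_vals, y, kept,
                                               panel_params)
            evaluation = evaluate_panel(sub_vals, y, panel, panel_params)
        except Exception:
            continue
        payload = {"disease": disease, "panel": panel,
                   "frequencies": {p: int(freqs[p]) for p in panel},
                   "mean_auc": evaluation["mean_auc"],
                   "ci95": evaluation["ci95"]}
        (out / f"panel_{disease}.json").write_text(json.dumps(payload))
        panel_done.append(disease)
    record("panel", [f"panel_{d}.json" for d in panel_done])

    manifest = {"seed": seed, "stages": stages}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
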