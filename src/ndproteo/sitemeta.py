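"""Site-level sensitivity analyses: per-site fits pooled by REML
random-effects meta-analysis, joint models with site as fixed or random
effect, and concordance reports between model variants.

Only sites containing both cases and controls are eligible, and the same
eligible-site set is used for by-site and joint analyses of a contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import minimize_scalar
import statsmodels.api as sm

from .containers import AbundanceMatrix, DataError
from .association import fit_associations, bh_adjust, _build_design, \
    _contrast_samples


def reml_loglik(tau2: float, betas: np.ndarray, variances: np.ndarray
                ) -> float:
    """Restricted log-likelihood of the random-effects model at tau^2."""
    w = 1.0 / (variances + tau2)
    mu = np.sum(w * betas) / np.sum(w)
    return -0.5 * (np.sum(np.log(variances + tau2)) + np.log(np.sum(w))
                   + np.sum(w * (betas - mu) ** 2))


def reml_pool(betas, variances, tol: float = 1e-10) -> dict:
    """REML random-effects pooling of per-site estimates.

    Maximizes the restricted likelihood in tau^2 by bounded 1-D
    optimization; the pooled effect is the inverse-variance weighted mean at
    the REML tau^2, with a Wald z p-value.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(b) < 2:
        raise DataError("need >= 2 site estimates to pool")
    if (v <= 0).any():
        raise DataError("site variances must be positive")
    upper = max(10.0 * (b.var(ddof=1) + v.max()), 1e-3)
    res = minimize_scalar(lambda t: -reml_loglik(t, b, v),
                          bounds=(0.0, upper), method="bounded",
                          options={"xatol": tol})
    tau2 = float(res.x)
    if reml_loglik(0.0, b, v) >= reml_loglik(tau2, b, v):
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / se
    return {"beta": pooled, "se": se, "tau2": tau2,
            "p": 2.0 * float(st.norm.sf(abs(z))), "k_sites": len(b)}


def eligible_sites(metadata: pd.DataFrame, contrast: str,
                   control_label: str = "control") -> list:
    """Sites that contain both cases and controls for the contrast."""
    out = []
    for site, sub in metadata.groupby("site"):
        diag = set(sub["diagnosis"])
        if contrast in diag and control_label in diag:
            out.append(site)
    return sorted(out)


def by_site_meta(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                 covariates: list, contrast: str,
                 covariate_table: pd.DataFrame | None = None,
                 control_label: str = "control"):
    """Fit the covariate-adjusted model independently within each eligible
    site and pool per-aptamer effects across sites by REML.

    Returns ``(meta_table, info)``; sites lacking either arm are excluded
    and listed in ``info["excluded_sites"]``; per-site fit failures drop the
    site for that aptamer and are counted.
    """
    sites = eligible_sites(metadata, contrast, control_label)
    excluded = sorted(set(metadata["site"]) - set(sites))
    if len(sites) < 2:
        raise DataError(f"need >= 2 eligible sites, got {sites}")
    per_site = {}
    for site in sites:
        meta_s = metadata[metadata["site"] == site]
        sub = AbundanceMatrix(matrix.values.loc[
            matrix.sample_ids.intersection(meta_s.index)],
            scale=matrix.scale,
            groups=matrix.groups)
        try:
            per_site[site] = fit_associations(
                sub, meta_s, covariates, contrast,
                covariate_table=covariate_table,
                control_label=control_label).set_index("aptamer")
        except DataError:
            excluded.append(site)
    if len(per_site) < 2:
        raise DataError("fewer than 2 sites produced usable fits")

    rows = []
    dropped = 0
    for apt in matrix.aptamer_ids:
        bs, vs = [], []
        for site, tab in per_site.items():
            b, s = tab.loc[apt, "beta"], tab.loc[apt, "se"]
            if np.isfinite(b) and np.isfinite(s) and s > 0:
                bs.append(b)
                vs.append(s ** 2)
            else:
                dropped += 1
        if len(bs) >= 2:
            rows.append({"aptamer": apt, **reml_pool(bs, vs)})
        else:
            rows.append({"aptamer": apt, "beta": np.nan, "se": np.nan,
                         "tau2": np.nan, "p": np.nan, "k_sites": len(bs)})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])
    info = {"sites": sorted(per_site), "excluded_sites": sorted(set(excluded)),
            "site_fit_failures": dropped}
    return table, info


def joint_site_models(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                      covariates: list, contrast: str,
                      site_mode: str = "fixed",
                      covariate_table: pd.DataFrame | None = None,
                      control_label: str = "control") -> pd.DataFrame:
    """Joint model over all eligible sites with site as fixed-effect
    covariate dummies or as a random intercept (REML linear mixed model)."""
    if site_mode not in ("fixed", "random"):
        raise DataError(f"site_mode must be 'fixed' or 'random', got "
                        f"{site_mode!r}")
    sites = eligible_sites(metadata, contrast, control_label)
    meta = metadata[metadata["site"].isin(sites)]
    if site_mode == "fixed":
        if len(sites) < 2:
            # site term uninformative; fall back to the plain model
            import warnings
            warnings.warn("single eligible site; site term dropped")
            covs = list(covariates)
        else:
            covs = list(covariates) + ["site"]
        sub = AbundanceMatrix(matrix.values.loc[
            matrix.sample_ids.intersection(meta.index)],
            scale=matrix.scale, groups=matrix.groups)
        return fit_associations(sub, meta, covs, contrast,
                                covariate_table=covariate_table,
                                control_label=control_label)

    if len(sites) < 2:
        raise DataError("random-intercept model needs >= 2 sites")
    case_ids, control_ids = _contrast_samples(meta, contrast, control_label)
    samples = matrix.sample_ids.intersection(case_ids.append(control_ids))
    status = meta.loc[samples, "diagnosis"].eq(contrast).to_numpy(float)
    cov_cols = _build_design(meta, samples, covariates, covariate_table)
    X = np.column_stack([np.ones(len(samples)), status]
                        + [np.asarray(v, float) for v in cov_cols.values()])
    groups_arr = meta.loc[samples, "site"].to_numpy()
    rows = []
    for apt in matrix.aptamer_ids:
        y = matrix.values.loc[samples, apt].to_numpy(dtype=float)
        row = {"aptamer": apt, "contrast": contrast, "beta": np.nan,
               "se": np.nan, "p": np.nan,
               "n_case": int(status.sum()),
               "n_control": int(len(samples) - status.sum()), "note": ""}
        try:
            with np.errstate(all="ignore"):
                model = sm.MixedLM(y, X, groups=groups_arr)
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            beta, se = fit.fe_params[1], fit.bse_fe[1]
            z = beta / se
            row.update({"beta": float(beta), "se": float(se),
                        "p": 2.0 * float(st.norm.sf(abs(z)))})
        except (np.linalg.LinAlgError, ValueError):
            row["note"] = "mixed_model_failure"
        rows.append(row)
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])
    return table


def model_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      q_threshold: float = 0.05,
                      p_threshold: float = 0.05) -> dict:
    """Concordance report between two association model variants: effect
    r^2, direction agreement, significance counts and overlap."""
    merged = pd.merge(table_a[["aptamer", "beta", "p", "q"]],
                      table_b[["aptamer", "beta", "p", "q"]],
                      on="aptamer", suffixes=("_a", "_b")).dropna()
    if merged.empty:
        raise DataError("no shared aptamers between the two tables")
    x, y = merged["beta_a"].to_numpy(), merged["beta_b"].to_numpy()
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2) if len(merged) > 2 else np.nan
    same_dir = (np.sign(x) == np.sign(y)) & (x != 0) & (y != 0)
    sig_a = merged["q_a"] < q_threshold
    sig_b = merged["q_b"] < q_threshold
    either = (sig_a | sig_b).sum()
    return {
        "r2": r2,
        "percent_same_direction": 100.0 * same_dir.mean(),
        "n_nominal_a": int((merged["p_a"] < p_threshold).sum()),
        "n_nominal_b": int((merged["p_b"] < p_threshold).sum()),
        "n_fdr_a": int(sig_a.sum()),
        "n_fdr_b": int(sig_b.sum()),
        "percent_significant_overlap": (
            100.0 * (sig_a & sig_b).sum() / either if either else np.nan),
        "n": int(len(merged)),
    }
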