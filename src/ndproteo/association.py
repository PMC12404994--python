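"""Per-aptamer differential abundance and tertile odds-ratio analysis.

Each aptamer is regressed on a case/control indicator plus covariates
(typically age, sex and the first two proteomic principal components) with
ordinary least squares on z-scored log10 abundance; p-values come from the
usual t statistic and are Benjamini-Hochberg adjusted across all aptamers in
the contrast. The covariate list is configurable (e.g. a no-sex model for
contrasts where sex is unavailable at a site).

The tertile odds-ratio analysis contextualizes effect sizes: samples in the
top vs bottom third of an aptamer's abundance are compared with logistic
regression (middle tertile excluded), and a "symmetric mean OR" summarizes
magnitudes after inverting ORs below 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import AbundanceMatrix, DataError, SCALE_ZSCORE


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _build_design(metadata: pd.DataFrame, samples: pd.Index,
                  covariates: list, covariate_table: pd.DataFrame | None):
    """Covariate design columns (no intercept, no status)."""
    cols = {}
    for cov in covariates:
        if cov in metadata.columns:
            series = metadata.loc[samples, cov]
        elif covariate_table is not None and cov in covariate_table.columns:
            series = covariate_table.loc[samples, cov]
        else:
            raise DataError(f"covariate {cov!r} not found in metadata or "
                            "covariate table")
        if series.dtype == object or str(series.dtype) == "category":
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True,
                                     dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[cov] = series.to_numpy(dtype=float)
    return cols


def _contrast_samples(metadata: pd.DataFrame, contrast: str,
                      control_label: str):
    case_ids = metadata.index[metadata["diagnosis"] == contrast]
    control_ids = metadata.index[metadata["diagnosis"] == control_label]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise DataError(f"contrast {contrast!r} needs >= 2 samples per arm "
                        f"(got {len(case_ids)} cases, {len(control_ids)} "
                        "controls)")
    return case_ids, control_ids


def fit_associations(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                     covariates: list, contrast: str,
                     covariate_table: pd.DataFrame | None = None,
                     control_label: str = "control") -> pd.DataFrame:
    """OLS case-vs-control effect per aptamer with covariate adjustment.

    Returns a table with columns ``aptamer, contrast, beta, se, p, q,
    n_case, n_control, note``. Fit failures (e.g. collinear design) are
    recorded as flagged rows, never silently dropped.
    """
    if matrix.scale != SCALE_ZSCORE:
        raise DataError("associations expect a z-scored matrix")
    case_ids, control_ids = _contrast_samples(metadata, contrast,
                                              control_label)
    samples = case_ids.append(control_ids)
    samples = matrix.sample_ids.intersection(samples)
    status = metadata.loc[samples, "diagnosis"].eq(contrast).to_numpy(float)
    n_case = int(status.sum())
    n_control = int(len(samples) - n_case)

    cov_cols = _build_design(metadata, samples, covariates, covariate_table)
    X = np.column_stack([np.ones(len(samples)), status]
                        + [v for v in cov_cols.values()])
    Y = matrix.values.loc[samples].to_numpy(dtype=float)
    m = Y.shape[1]
    note = ""
    if np.isnan(Y).any():
        raise DataError("association fits expect a complete (imputed) matrix")

    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p or n <= p:
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        pv = np.full(m, np.nan)
        note = "collinear_design" if rank < p else "insufficient_df"
    else:
        xtx_inv = np.linalg.inv(X.T @ X)
        coef = xtx_inv @ X.T @ Y                      # (p, m)
        resid = Y - X @ coef
        dof = n - p
        sigma2 = (resid ** 2).sum(axis=0) / dof
        beta = coef[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(sigma2 * xtx_inv[1, 1])
            tstat = beta / se
        pv = 2.0 * st.t.sf(np.abs(tstat), dof)
        pv[~np.isfinite(tstat)] = np.nan

    table = pd.DataFrame({
        "aptamer": matrix.aptamer_ids, "contrast": contrast,
        "beta": beta, "se": se, "p": pv, "q": bh_adjust(pv),
        "n_case": n_case, "n_control": n_control, "note": note,
    })
    return table


def tertile_assignments(values: np.ndarray) -> np.ndarray:
    """Tertile index (0, 1, 2) by empirical rank, ties broken by stable
    order of appearance."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 3) // n


def tertile_odds_ratios(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                        covariates: list, contrast: str,
                        aptamer_subset: list | None = None,
                        covariate_table: pd.DataFrame | None = None,
                        control_label: str = "control"):
    """Logistic OR of disease for top- vs bottom-tertile abundance.

    Tertiles are computed on the analyzed (case + control) samples per
    aptamer; the middle tertile is excluded. Returns ``(table, summary)``
    where ``summary['symmetric_mean_or']`` is the mean OR after inverting
    ORs below 1.
    """
    case_ids, control_ids = _contrast_samples(metadata, contrast,
                                              control_label)
    samples = matrix.sample_ids.intersection(case_ids.append(control_ids))
    status_all = metadata.loc[samples, "diagnosis"].eq(contrast) \
        .to_numpy(float)
    cov_cols = _build_design(metadata, samples, covariates, covariate_table)
    cov_arr = (np.column_stack(list(cov_cols.values()))
               if cov_cols else np.empty((len(samples), 0)))
    aptamers = (list(aptamer_subset) if aptamer_subset is not None
                else list(matrix.aptamer_ids))
    missing = [a for a in aptamers if a not in matrix.aptamer_ids]
    if missing:
        raise DataError(f"aptamers not in matrix: {missing[:5]}")

    rows = []
    zcrit = st.norm.ppf(0.975)
    for apt in aptamers:
        vals = matrix.values.loc[samples, apt].to_numpy(dtype=float)
        tert = tertile_assignments(vals)
        keep = tert != 1
        y = status_all[keep]
        x = (tert[keep] == 2).astype(float)
        X = np.column_stack([np.ones(keep.sum()), x, cov_arr[keep]])
        row = {"aptamer": apt, "contrast": contrast, "or": np.nan,
               "ci95_low": np.nan, "ci95_high": np.nan, "p": np.nan,
               "note": ""}
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            coef, sev = fit.params[1], fit.bse[1]
            if not np.isfinite(sev) or sev > 50:
                raise PerfectSeparationError("quasi-separation")
            row.update({"or": float(np.exp(coef)),
                        "ci95_low": float(np.exp(coef - zcrit * sev)),
                        "ci95_high": float(np.exp(coef + zcrit * sev)),
                        "p": float(fit.pvalues[1])})
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            row["note"] = "separation_or_fit_failure"
            row["ci95_low"], row["ci95_high"] = 0.0, np.inf
        rows.append(row)
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])
    ors = table["or"].dropna()
    symmetric = np.where(ors < 1.0, 1.0 / ors, ors)
    summary = {"symmetric_mean_or": float(symmetric.mean())
               if len(symmetric) else np.nan,
               "n_fitted": int(len(ors)),
               "n_flagged": int((table["note"] != "").sum())}
    return table, summary
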