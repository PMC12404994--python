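"""Quality control and harmonization of multi-site aptamer data.

Stages, in the order the pipeline applies them: log10 transform, IQR-fence
outlier masking within each processing group, two-pass call-rate filtering
(65% then a stringent 85%), removal of aptamers targeting non-human proteins
or lacking annotation, bootstrap imputation of remaining missing values,
group-wise z-score normalization (pooled EDTA samples and each citrate site
separately), and proteomic principal components for use as covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (AbundanceMatrix, QCReport, DataError, PipelineError,
                         SpecificationError, rng_for,
                         SCALE_RFU, SCALE_LOG10, SCALE_ZSCORE)


@dataclass
class QCParams:
    """Thresholds of the QC chain.

    ``iqr_multiplier`` fences are strict: only values strictly beyond
    Q1 - k*IQR or Q3 + k*IQR are masked, so an IQR of zero masks nothing.
    ``quantile_method`` is any method accepted by :func:`numpy.quantile`
    (default ``"linear"``, i.e. the type-7 convention).
    """

    iqr_multiplier: float = 1.5
    pass1_call_rate: float = 0.65
    pass2_call_rate: float = 0.85
    quantile_method: str = "linear"
    per_group_fences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pass1_call_rate <= self.pass2_call_rate <= 1.0):
            raise SpecificationError(
                "need 0 < pass1_call_rate <= pass2_call_rate <= 1")
        if self.iqr_multiplier <= 0:
            raise SpecificationError("iqr_multiplier must be positive")


def log10_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log10-transform observed RFU values (missing entries untouched)."""
    if matrix.scale != SCALE_RFU:
        raise DataError(f"expected RFU-scale matrix, got {matrix.scale}")
    bad = (matrix.values <= 0)
    if bad.any().any():
        cells = [(i, j) for i, j in zip(*np.nonzero(bad.to_numpy()))]
        named = [(matrix.sample_ids[i], matrix.aptamer_ids[j])
                 for i, j in cells[:10]]
        raise DataError(f"non-positive RFU values at {named}"
                        + (" ..." if len(cells) > 10 else ""))
    out = matrix.copy()
    out.values = np.log10(matrix.values)
    out.scale = SCALE_LOG10
    return out


def mask_outliers_iqr(matrix: AbundanceMatrix, params: QCParams | None = None):
    """Mask entries strictly outside [Q1 - k*IQR, Q3 + k*IQR].

    Fences are computed per aptamer within each processing group (or across
    all samples with ``per_group_fences=False``). Aptamer/group combinations
    with fewer than 4 observed values are skipped — quartile fences are not
    meaningful there — and logged in the report.
    """
    params = params or QCParams()
    if matrix.scale != SCALE_LOG10:
        raise DataError("outlier masking expects a log10-scale matrix")
    out = matrix.copy()
    report = QCReport()
    vals = out.values.to_numpy(copy=True)
    group_iter = (out.groups.groupby(out.groups).groups.items()
                  if params.per_group_fences
                  else [("all", out.values.index)])
    for group, idx in group_iter:
        rows = out.values.index.get_indexer(idx)
        sub = vals[rows, :]
        n_obs = (~np.isnan(sub)).sum(axis=0)
        enough = n_obs >= 4
        for apt in np.flatnonzero(~enough):
            report.skipped_aptamer_groups.append(
                (str(group), out.values.columns[apt]))
        if not enough.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q1 = np.nanquantile(sub, 0.25, axis=0,
                                method=params.quantile_method)
            q3 = np.nanquantile(sub, 0.75, axis=0,
                                method=params.quantile_method)
        iqr = q3 - q1
        lo = q1 - params.iqr_multiplier * iqr
        hi = q3 + params.iqr_multiplier * iqr
        with np.errstate(invalid="ignore"):
            mask = ((sub < lo[None, :]) | (sub > hi[None, :])) & enough[None, :]
        report.masked_outlier_count += int(mask.sum())
        sub[mask] = np.nan
        vals[rows, :] = sub
    out.values = pd.DataFrame(vals, index=out.values.index,
                              columns=out.values.columns)
    report.final_dims = out.values.shape
    return out, report


def call_rate_filter(matrix: AbundanceMatrix, params: QCParams | None = None):
    """Two-pass call-rate filter.

    Each pass removes analytes below the threshold (evaluated on the samples
    entering the pass), then samples below the threshold (evaluated on the
    surviving analytes). Pass 1 at 65%, pass 2 at 85% after recomputation.
    """
    params = params or QCParams()
    out = matrix.copy()
    report = QCReport()
    for passno, threshold in ((1, params.pass1_call_rate),
                              (2, params.pass2_call_rate)):
        analyte_cr = out.analyte_call_rates()
        drop_analytes = analyte_cr.index[analyte_cr < threshold].tolist()
        out.values = out.values.drop(columns=drop_analytes)
        sample_cr = out.sample_call_rates() if out.values.shape[1] else \
            pd.Series(dtype=float)
        drop_samples = sample_cr.index[sample_cr < threshold].tolist()
        out.values = out.values.drop(index=drop_samples)
        out.groups = out.groups.drop(index=drop_samples)
        if passno == 1:
            report.removed_analytes_pass1 = drop_analytes
            report.removed_samples_pass1 = drop_samples
        else:
            report.removed_analytes_pass2 = drop_analytes
            report.removed_samples_pass2 = drop_samples
    if out.values.size == 0:
        raise PipelineError("matrix is empty after call-rate filtering")
    report.final_dims = out.values.shape
    return out, report


def drop_nonhuman(matrix: AbundanceMatrix, annotation: pd.DataFrame):
    """Remove aptamers targeting non-human proteins or lacking annotation."""
    ann = annotation.set_index("aptamer_id")
    removed = []
    for apt in matrix.aptamer_ids:
        if apt not in ann.index:
            removed.append(apt)
            continue
        organism = ann.loc[apt].get("organism")
        protein = ann.loc[apt].get("protein")
        if (not isinstance(organism, str) or organism.lower() != "human"
                or not isinstance(protein, str) or not protein.strip()):
            removed.append(apt)
    out = matrix.copy()
    out.values = out.values.drop(columns=removed)
    report = QCReport(removed_nonhuman=removed, final_dims=out.values.shape)
    return out, report


def impute_bootstrap(matrix: AbundanceMatrix, seed: int = 0) -> AbundanceMatrix:
    """Replace each missing entry with a value drawn (with replacement) from
    the non-missing values of the same aptamer. Seeded and reproducible."""
    out = matrix.copy()
    vals = out.values.to_numpy(copy=True)
    rng = rng_for(seed, "impute")
    for j, apt in enumerate(out.values.columns):
        col = vals[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        observed = col[~missing]
        if observed.size == 0:
            raise DataError(f"aptamer {apt} has no observed values to "
                            "impute from")
        col[missing] = rng.choice(observed, size=int(missing.sum()),
                                  replace=True)
        vals[:, j] = col
    out.values = pd.DataFrame(vals, index=out.values.index,
                              columns=out.values.columns)
    return out


def zscore_by_group(matrix: AbundanceMatrix, ddof: int = 1):
    """z-score each aptamer within each processing group (mean 0, s.d. 1).

    Zero-variance aptamer/group combinations are set to 0 and reported.
    Uses the sample (n-1) standard deviation by default.
    """
    if matrix.scale != SCALE_LOG10:
        raise DataError("z-scoring expects a log10-scale matrix")
    if matrix.values.isna().any().any():
        raise DataError("z-scoring expects a complete (imputed) matrix")
    out = matrix.copy()
    report = QCReport()
    vals = out.values.to_numpy(copy=True)
    for group, idx in out.groups.groupby(out.groups).groups.items():
        rows = out.values.index.get_indexer(idx)
        sub = vals[rows, :]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=ddof) if sub.shape[0] > ddof else \
            np.zeros(sub.shape[1])
        zero = sd == 0
        sd_safe = np.where(zero, 1.0, sd)
        vals[rows, :] = (sub - mean[None, :]) / sd_safe[None, :]
        if zero.any():
            for apt in out.values.columns[zero]:
                report.zero_variance_aptamers.append((str(group), apt))
            vals[np.ix_(rows, np.flatnonzero(zero))] = 0.0
    if report.zero_variance_aptamers:
        warnings.warn(f"{len(report.zero_variance_aptamers)} zero-variance "
                      "aptamer/group combinations set to 0")
    out.values = pd.DataFrame(vals, index=out.values.index,
                              columns=out.values.columns)
    out.scale = SCALE_ZSCORE
    report.final_dims = out.values.shape
    return out, report


def compute_pcs(matrix: AbundanceMatrix, k: int = 2) -> pd.DataFrame:
    """First ``k`` proteomic principal-component scores per sample.

    Deterministic up to sign; the sign of each component is fixed by making
    its largest-magnitude loading positive.
    """
    if matrix.values.isna().any().any():
        raise DataError("PCA expects a complete (imputed) matrix")
    if k >= min(matrix.values.shape):
        raise SpecificationError(f"k={k} must be < min(matrix dims)")
    x = matrix.values.to_numpy()
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    for comp in range(k):
        lead = np.argmax(np.abs(loadings[comp]))
        if loadings[comp, lead] < 0:
            scores[:, comp] *= -1
            loadings[comp] *= -1
    return pd.DataFrame(scores, index=matrix.values.index,
                        columns=[f"PC{i + 1}" for i in range(k)])


def run_qc(matrix: AbundanceMatrix, annotation: pd.DataFrame,
           params: QCParams | None = None, n_pcs: int = 2):
    """Full QC chain: log10 -> outlier masking -> call-rate filtering ->
    non-human removal -> bootstrap imputation -> group z-scoring -> PCs.

    Returns ``(zscored_matrix, pcs, report)`` with a merged QC report.
    """
    params = params or QCParams()
    logm = log10_transform(matrix)
    masked, rep_mask = mask_outliers_iqr(logm, params)
    filtered, rep_cr = call_rate_filter(masked, params)
    human, rep_nh = drop_nonhuman(filtered, annotation)
    imputed = impute_bootstrap(human, seed=params.seed)
    zscored, rep_z = zscore_by_group(imputed)
    pcs = compute_pcs(zscored, k=n_pcs)
    report = QCReport(
        masked_outlier_count=rep_mask.masked_outlier_count,
        skipped_aptamer_groups=rep_mask.skipped_aptamer_groups,
        removed_analytes_pass1=rep_cr.removed_analytes_pass1,
        removed_samples_pass1=rep_cr.removed_samples_pass1,
        removed_analytes_pass2=rep_cr.removed_analytes_pass2,
        removed_samples_pass2=rep_cr.removed_samples_pass2,
        removed_nonhuman=rep_nh.removed_nonhuman,
        zero_variance_aptamers=rep_z.zero_variance_aptamers,
        final_dims=zscored.values.shape,
    )
    return zscored, pcs, report
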