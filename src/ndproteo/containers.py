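"""Core in-memory containers shared by all pipeline stages.

The central object is :class:`AbundanceMatrix`: a samples x aptamers table of
plasma protein measurements with an explicit missingness mask (NaN), a scale
tag tracking where the matrix sits in the RFU -> log10 -> z-score chain, and a
per-sample processing-group label (pooled EDTA vs per-site citrate) that QC
and normalization operate within.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

SCALE_RFU = "RFU"
SCALE_LOG10 = "log10"
SCALE_ZSCORE = "zscore"

_VALID_SCALES = (SCALE_RFU, SCALE_LOG10, SCALE_ZSCORE)


class SpecificationError(ValueError):
    """A parameter or configuration violates its documented constraints."""


class DataError(ValueError):
    """Input data violate a precondition (wrong scale, bad values...)."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. empty matrix after filtering)."""


@dataclass
class AbundanceMatrix:
    """Sample x aptamer abundance values with missingness and group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by sample id, columns by aptamer id. NaN marks a
        missing measurement.
    scale : str
        One of ``"RFU"``, ``"log10"``, ``"zscore"``.
    groups : pandas.Series
        Processing-group label per sample (index aligned with ``values``).
        EDTA samples from all contributors share one pooled group; each
        citrate contributor forms its own group.
    """

    values: pd.DataFrame
    scale: str = SCALE_RFU
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise SpecificationError(
                f"scale must be one of {_VALID_SCALES}, got {self.scale!r}")
        if self.groups is None:
            self.groups = pd.Series("EDTA", index=self.values.index)
        else:
            self.groups = self.groups.reindex(self.values.index)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()].tolist()
                raise DataError(f"samples without group label: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_aptamers(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def aptamer_ids(self) -> pd.Index:
        return self.values.columns

    def observed_mask(self) -> pd.DataFrame:
        return self.values.notna()

    def sample_call_rates(self) -> pd.Series:
        """Fraction of non-missing analytes per sample."""
        return self.values.notna().mean(axis=1)

    def analyte_call_rates(self) -> pd.Series:
        """Fraction of non-missing samples per analyte."""
        return self.values.notna().mean(axis=0)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.scale,
                               self.groups.copy())


@dataclass
class QCReport:
    """Record of what quality control removed, masked or warned about."""

    masked_outlier_count: int = 0
    skipped_aptamer_groups: list = field(default_factory=list)
    removed_analytes_pass1: list = field(default_factory=list)
    removed_samples_pass1: list = field(default_factory=list)
    removed_analytes_pass2: list = field(default_factory=list)
    removed_samples_pass2: list = field(default_factory=list)
    removed_nonhuman: list = field(default_factory=list)
    zero_variance_aptamers: list = field(default_factory=list)
    final_dims: tuple = (0, 0)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["final_dims"] = list(self.final_dims)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def validate_fraction(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise SpecificationError(f"{name} must be in [0, 1], got {value}")


def validate_positive(value, name: str) -> None:
    if not value > 0:
        raise SpecificationError(f"{name} must be positive, got {value}")


def derive_seed(seed: int, stream: str) -> int:
    """Deterministically derive a sub-seed (< 2**31) for a named stream."""
    import zlib
    return (int(seed) * 1_000_003 + zlib.crc32(stream.encode())) % (2**31 - 1)


def rng_for(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, stream))
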