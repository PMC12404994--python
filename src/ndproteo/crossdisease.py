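"""Shared vs disease-specific signatures across association tables.

Provides the overlap partition of significant aptamers across diseases,
pairwise effect-size correlation with a 95% band around the regression line
(prediction band by default — the band that visually bounds points in a
scatter), and directional concordance between two association tables (used
for sensitivity analyses and cross-platform validation-style comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import DataError


def _check_universe(tables: dict):
    universes = {name: frozenset(tab["aptamer"]) for name, tab in
                 tables.items()}
    ref_name, ref = next(iter(universes.items()))
    for name, uni in universes.items():
        if uni != ref:
            diff = sorted(uni.symmetric_difference(ref))
            raise DataError(
                f"aptamer universes differ between {ref_name!r} and "
                f"{name!r}; symmetric difference (first 10): {diff[:10]}")


def overlap_sets(tables: dict, q_threshold: float = 0.05) -> dict:
    """Partition the union of significant aptamers by significance pattern.

    Returns ``{"patterns": {frozenset(diseases): [aptamers]}, "counts":
    {...}, "percent": {...}, "union_size": int}``; the pattern sets
    partition the union exactly.
    """
    _check_universe(tables)
    sig = {name: set(tab.loc[tab["q"] < q_threshold, "aptamer"])
           for name, tab in tables.items()}
    union = set().union(*sig.values())
    patterns: dict = {}
    for apt in sorted(union):
        key = frozenset(d for d, s in sig.items() if apt in s)
        patterns.setdefault(key, []).append(apt)
    counts = {key: len(v) for key, v in patterns.items()}
    percent = {key: 100.0 * c / len(union) if union else 0.0
               for key, c in counts.items()}
    return {"patterns": patterns, "counts": counts, "percent": percent,
            "union_size": len(union)}


@dataclass
class EffectComparison:
    pair: tuple
    data: pd.DataFrame                # aptamer, beta_x, beta_y, class, outside
    r2: float
    slope: float
    intercept: float
    outside_band: list
    direction_summary: dict = field(default_factory=dict)
    band_kind: str = "prediction"


def effect_size_correlation(table_x: pd.DataFrame, table_y: pd.DataFrame,
                            selection_rule: str = "union_significant",
                            q_threshold: float = 0.05,
                            band: str = "prediction") -> EffectComparison:
    """Pairwise effect-size comparison between two disease tables.

    ``selection_rule`` picks the aptamers entering the correlation:
    ``union_significant`` (significant in either), ``both_significant``, or
    ``all``. The 95% band is around the OLS line of beta_y on beta_x:
    ``prediction`` (individual points, default) or ``mean`` (mean response).
    The direction summary counts sign agreement among both-significant
    aptamers.
    """
    if selection_rule not in ("union_significant", "both_significant", "all"):
        raise DataError(f"unknown selection_rule {selection_rule!r}")
    _check_universe({"x": table_x, "y": table_y})
    merged = pd.merge(
        table_x[["aptamer", "beta", "q"]].rename(
            columns={"beta": "beta_x", "q": "q_x"}),
        table_y[["aptamer", "beta", "q"]].rename(
            columns={"beta": "beta_y", "q": "q_y"}),
        on="aptamer").dropna(subset=["beta_x", "beta_y"])
    sig_x = merged["q_x"] < q_threshold
    sig_y = merged["q_y"] < q_threshold
    merged["class"] = np.select(
        [sig_x & sig_y, sig_x & ~sig_y, ~sig_x & sig_y],
        ["both", "x_only", "y_only"], default="neither")
    if selection_rule == "union_significant":
        sel = merged[sig_x | sig_y].copy()
    elif selection_rule == "both_significant":
        sel = merged[sig_x & sig_y].copy()
    else:
        sel = merged.copy()
    if len(sel) < 3:
        raise DataError(f"only {len(sel)} aptamers selected; need >= 3")

    x = sel["beta_x"].to_numpy()
    y = sel["beta_y"].to_numpy()
    res = st.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    n = len(x)
    yhat = res.intercept + res.slope * x
    resid = y - yhat
    s = np.sqrt((resid ** 2).sum() / (n - 2))
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    tcrit = st.t.ppf(0.975, n - 2)
    lever = 1.0 / n + (x - xbar) ** 2 / sxx
    if band == "prediction":
        half = tcrit * s * np.sqrt(1.0 + lever)
    elif band == "mean":
        half = tcrit * s * np.sqrt(lever)
    else:
        raise DataError(f"unknown band {band!r}")
    outside = np.abs(resid) > half
    sel["outside_band"] = outside

    shared = merged[merged["class"] == "both"]
    summary = {
        "both_up": int(((shared["beta_x"] > 0) & (shared["beta_y"] > 0)).sum()),
        "both_down": int(((shared["beta_x"] < 0)
                          & (shared["beta_y"] < 0)).sum()),
    }
    summary["opposite"] = int(len(shared) - summary["both_up"]
                              - summary["both_down"])
    return EffectComparison(
        pair=(table_x["contrast"].iloc[0], table_y["contrast"].iloc[0]),
        data=sel.reset_index(drop=True), r2=r2, slope=float(res.slope),
        intercept=float(res.intercept),
        outside_band=sel.loc[outside, "aptamer"].tolist(),
        direction_summary=summary, band_kind=band)


def directional_concordance(table_ref: pd.DataFrame, table_alt: pd.DataFrame,
                            aptamer_subset) -> dict:
    """Percent of aptamers whose effects point the same way in both tables.

    Exact zeros never count as concordant; they are tallied separately and
    counted in the denominator (i.e. as discordant).
    """
    subset = list(aptamer_subset)
    if not subset:
        raise DataError("aptamer_subset is empty")
    ref = table_ref.set_index("aptamer")["beta"]
    alt = table_alt.set_index("aptamer")["beta"]
    missing = [a for a in subset if a not in ref.index or a not in alt.index]
    if missing:
        raise DataError(f"subset aptamers missing from tables: {missing[:5]}")
    r = ref.loc[subset].to_numpy()
    a = alt.loc[subset].to_numpy()
    zero = (r == 0) | (a == 0)
    concordant = (np.sign(r) == np.sign(a)) & ~zero
    return {
        "percent_concordant": 100.0 * concordant.sum() / len(subset),
        "n": len(subset),
        "n_concordant": int(concordant.sum()),
        "n_discordant": int((~concordant & ~zero).sum()),
        "n_zero_effect": int(zero.sum()),
    }


def pairwise_comparisons(tables: dict, **kwargs) -> dict:
    """Effect comparisons for every disease pair in ``tables``."""
    return {(a, b): effect_size_correlation(tables[a], tables[b], **kwargs)
            for a, b in combinations(sorted(tables), 2)}
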