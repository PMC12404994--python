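"""Over-representation analysis and cell-type specificity enrichment.

Pathway-style enrichment is a one-sided hypergeometric test of a query gene
list against user-supplied gene sets (GMT), with optional BH correction.
Cell-type analysis first labels genes as specific to the cell type where
they are expressed at least ``ratio`` times higher than in any other cell
type (brain references use mean expression; blood references use pseudobulk
proportions), then tests the query for enrichment of each label with either
the hypergeometric upper tail or Fisher's exact test with the cross-product
odds ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import DataError
from .association import bh_adjust


def map_aptamers_to_genes(aptamers, annotation: pd.DataFrame) -> list:
    """Expand aptamer ids to unique gene symbols; multi-target annotations
    such as ``"UBE2D1 | UBB"`` contribute each listed symbol once."""
    ann = annotation.set_index("aptamer_id")["protein"]
    genes = []
    for apt in aptamers:
        if apt not in ann.index or not isinstance(ann.loc[apt], str):
            continue
        for sym in ann.loc[apt].split("|"):
            sym = sym.strip()
            if sym:
                genes.append(sym)
    return sorted(set(genes))


def hypergeom_enrich(query_genes, gene_sets: dict,
                     universe=None, correction: str = "BH") -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query_genes`` in
    each gene set.

    The universe defaults to the union of all set members; query genes
    outside the universe are dropped (and counted in the ``n_query_dropped``
    attribute of the result). p = P(X >= overlap) for X hypergeometric with
    population ``|universe|``, successes ``|set|``, draws ``|query|``.
    """
    if correction not in ("BH", "none"):
        raise DataError(f"correction must be 'BH' or 'none', got "
                        f"{correction!r}")
    if universe is None:
        universe = set().union(*gene_sets.values())
    universe = set(universe)
    query = set(query_genes)
    dropped = query - universe
    query &= universe
    if not query:
        raise DataError("query is empty after intersecting with universe")
    big_n, n_draw = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            continue
        k = len(members & query)
        p = float(st.hypergeom.sf(k - 1, big_n, len(members), n_draw))
        rows.append({"set": name, "overlap": k, "set_size": len(members),
                     "query_size": n_draw, "universe_size": big_n,
                     "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"]) if correction == "BH" else table["p"]
    table.attrs["n_query_dropped"] = len(dropped)
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def assign_specificity(reference: pd.DataFrame, mode: str = "brain_ratio",
                       ratio: float = 1.5) -> pd.Series:
    """Label each gene with its top cell type when that cell type's value is
    at least ``ratio`` times the second-highest; otherwise leave unlabeled.

    ``brain_ratio`` applies the rule to mean expression; ``blood_proportion``
    first converts each gene's row to proportions across cell types (the
    pseudobulk convention) — the labeling itself is ratio-invariant, but the
    returned reference values differ. All-zero genes stay unlabeled.
    """
    if mode not in ("brain_ratio", "blood_proportion"):
        raise DataError(f"unknown specificity mode {mode!r}")
    if reference.shape[1] < 2:
        raise DataError("need >= 2 cell types")
    if (reference < 0).any().any():
        raise DataError("reference expression must be nonnegative")
    vals = reference.to_numpy(dtype=float)
    if mode == "blood_proportion":
        totals = vals.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(totals > 0, vals / totals, 0.0)
    order = np.argsort(vals, axis=1)
    top = vals[np.arange(len(vals)), order[:, -1]]
    second = vals[np.arange(len(vals)), order[:, -2]]
    labeled = (top > 0) & (top >= ratio * second)
    labels = pd.Series(
        np.where(labeled, reference.columns.to_numpy()[order[:, -1]], None),
        index=reference.index, dtype=object, name="cell_type")
    return labels


def celltype_enrich(query_genes, labels: pd.Series,
                    mode: str = "hypergeom") -> pd.DataFrame:
    """Per-cell-type enrichment of the query among labeled genes.

    For each cell type a 2x2 table of (in query) x (labeled that type) over
    the label universe is tested with the hypergeometric upper tail
    (``mode="hypergeom"``) or one-sided Fisher's exact test
    (``mode="fisher"``); the reported OR is always the sample cross-product
    ratio. Cell types with zero labeled genes are skipped.
    """
    if mode not in ("hypergeom", "fisher"):
        raise DataError(f"unknown enrichment mode {mode!r}")
    universe = set(labels.index)
    query = set(query_genes) & universe
    if not query:
        raise DataError("query is empty after intersecting with the labeled "
                        "universe")
    rows = []
    for ct in sorted({l for l in labels.dropna().unique()}):
        members = set(labels.index[labels == ct])
        if not members:
            continue
        a = len(members & query)                       # query & labeled
        b = len(query) - a                             # query & not labeled
        c = len(members) - a                           # labeled, not query
        d = len(universe) - a - b - c
        if mode == "hypergeom":
            p = float(st.hypergeom.sf(a - 1, len(universe), len(members),
                                      len(query)))
        else:
            _, p = st.fisher_exact([[a, b], [c, d]], alternative="greater")
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"cell_type": ct, "overlap": a, "set_size": len(members),
                     "query_size": len(query), "universe_size": len(universe),
                     "p": min(float(p), 1.0), "or": float(odds)})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"]) if len(table) else []
    return table.sort_values("p", kind="stable").reset_index(drop=True)
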