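"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats:

* abundance TSV — first column ``sample_id``, remaining columns aptamer ids;
  empty cell = missing measurement.
* metadata / annotation TSV — one row per sample / aptamer.
* GMT — tab-separated gene sets: name, description, member genes.
* interaction TSV — STRING-style: ``protein1``, ``protein2``, per-channel
  scores and a ``combined_score`` (0-1 or 0-1000).
* truth JSON — the synthetic generator's ground truth.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, DataError


def write_abundance_tsv(matrix: AbundanceMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_abundance_tsv(path, scale: str = "RFU",
                       groups: pd.Series | None = None) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return AbundanceMatrix(df, scale=scale, groups=groups)


def write_table_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str})
    if meta["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id rows in metadata")
    return meta.set_index("sample_id", drop=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    """Write gene sets in GMT format (name, description, members...)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + list(members)) + "\n")


def read_gmt(path) -> dict:
    sets: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


_STRING_CHANNELS = ["experimental", "database", "coexpression",
                    "neighborhood", "fusion", "cooccurence"]


def write_interactions_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_interactions_tsv(path) -> pd.DataFrame:
    """Read a STRING-style interaction table and normalize scores to [0, 1].

    A ``combined_score`` column given on STRING's customary 0-1000 integer
    scale is rescaled; deduplicates undirected pairs keeping the highest
    combined score.
    """
    tab = pd.read_csv(path, sep="\t")
    for col in ("protein1", "protein2", "combined_score"):
        if col not in tab.columns:
            raise DataError(f"interaction table missing column {col!r}")
    scores = tab["combined_score"].astype(float)
    if scores.max() > 1.0:
        scores = scores / 1000.0
    if (scores < 0).any() or (scores > 1).any():
        raise DataError("combined_score outside declared range")
    tab = tab.copy()
    tab["combined_score"] = scores
    a = tab[["protein1", "protein2"]].min(axis=1)
    b = tab[["protein1", "protein2"]].max(axis=1)
    tab["protein1"], tab["protein2"] = a, b
    tab = (tab.sort_values("combined_score", ascending=False)
              .drop_duplicates(["protein1", "protein2"], keep="first")
              .reset_index(drop=True))
    return tab


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_truth_json(truth, path) -> None:
    payload = {
        "true_beta": {
            "aptamers": truth.true_beta.index.tolist(),
            "diseases": truth.true_beta.columns.tolist(),
            "values": truth.true_beta.to_numpy().tolist(),
        },
        "true_site_offsets": dict(truth.true_site_offsets),
        "outlier_positions": [list(p) for p in truth.outlier_positions],
        "missing_positions": [list(p) for p in truth.missing_positions],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, cls=_TruthEncoder)


def read_truth_json(path):
    from .cohort import CohortTruth
    with open(path) as fh:
        payload = json.load(fh)
    tb = payload["true_beta"]
    beta = pd.DataFrame(tb["values"], index=tb["aptamers"],
                        columns=tb["diseases"])
    return CohortTruth(
        true_beta=beta,
        true_site_offsets=payload["true_site_offsets"],
        outlier_positions=[tuple(p) for p in payload["outlier_positions"]],
        missing_positions=[tuple(p) for p in payload["missing_positions"]],
    )
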