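import numpy as np
import pandas as pd
import pytest

import ndproteo as nd
from ndproteo.qc import log10_transform, zscore_by_group


def make_zscore_matrix(values: np.ndarray, sample_ids=None, columns=None,
                       groups=None) -> nd.AbundanceMatrix:
    """Wrap a raw array as an already-z-scored matrix for direct tests."""
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[0])]
    columns = columns or [f"A{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                      columns=columns)
    g = pd.Series(groups if groups is not None else "EDTA", index=df.index)
    return nd.AbundanceMatrix(df, scale="zscore", groups=g)


def simple_metadata(diagnoses, sample_ids=None, sites=None, ages=None,
                    sexes=None) -> pd.DataFrame:
    n = len(diagnoses)
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "diagnosis": list(diagnoses),
        "age": ages if ages is not None else np.full(n, 70.0),
        "sex": sexes if sexes is not None else (["F", "M"] * n)[:n],
        "site": sites if sites is not None else ["S01"] * n,
        "anticoagulant": "EDTA",
    })
    return meta.set_index("sample_id", drop=False)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-disease cohort with planted effects, shared block and
    QC challenges (missingness, outliers, non-human aptamers)."""
    spec = nd.CohortSpec(
        n_per_group={"control": 120, "AD": 60, "PD": 50},
        n_sites=4, citrate_sites=("S02",), n_aptamers=200,
        frac_signal=0.2, effect_scale=0.8,
        shared_block_spec={("AD", "PD"): {"frac_shared": 0.5,
                                          "r2_target": 0.5}},
        missing_rate=0.03, outlier_rate=0.003, n_nonhuman=4, seed=7)
    matrix, metadata, annotation, truth = nd.generate_cohort(spec)
    return {"spec": spec, "matrix": matrix, "metadata": metadata,
            "annotation": annotation, "truth": truth}


@pytest.fixture(scope="session")
def qc_cohort(small_cohort):
    z, pcs, report = nd.run_qc(small_cohort["matrix"],
                               small_cohort["annotation"],
                               nd.QCParams(seed=1))
    meta = small_cohort["metadata"].loc[z.sample_ids]
    return {"z": z, "pcs": pcs, "report": report, "metadata": meta,
            "truth": small_cohort["truth"]}


@pytest.fixture(scope="session")
def assoc_tables(qc_cohort):
    tables = {}
    for disease in ("AD", "PD"):
        tables[disease] = nd.fit_associations(
            qc_cohort["z"], qc_cohort["metadata"],
            ["age", "sex", "PC1", "PC2"], disease,
            covariate_table=qc_cohort["pcs"])
    return tables
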