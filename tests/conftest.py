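import numpy as np
import pandas as pd
import pytest

from omisurv import ClinicalTable, OmicsMatrix, SyntheticConfig, generate_cohort


def tiny_synthetic_config(seed=0, **overrides) -> SyntheticConfig:
    """Desk-scale config for fast unit tests (not the acceptance default)."""
    base = dict(
        n_common=120,
        n_uncommon_by_category={"RPPA": 40},
        feature_dims={
            "mRNA": 60, "miRNA": 40, "methylation": 60,
            "CNV": 50, "somatic_mutation": 50, "RPPA": 40,
        },
        signal_strength={
            "mRNA": 0.5, "miRNA": 0.5, "methylation": 0.5,
            "CNV": 0.0, "somatic_mutation": 0.0, "RPPA": 2.0,
        },
        n_informative={
            "mRNA": 6, "miRNA": 4, "methylation": 6,
            "CNV": 0, "somatic_mutation": 0, "RPPA": 5,
        },
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_synthetic_config(seed=7))


@pytest.fixture
def clinical_10():
    """Ten samples with interleaved censoring (hand-computable KM)."""
    return ClinicalTable(
        pd.DataFrame(
            {
                "time_days": [5, 8, 8, 12, 15, 20, 24, 30, 34, 40],
                "event": [1, 0, 1, 1, 0, 1, 0, 1, 0, 0],
                "histology": ["LUAD"] * 5 + ["LUSC"] * 5,
            },
            index=pd.Index([f"P{i}" for i in range(10)], name="sample_id"),
        )
    )


def make_matrix(values, category="RPPA", stage="raw", prefix="f"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return OmicsMatrix(
        category=category,
        values=pd.DataFrame(
            values,
            index=[f"S{i}" for i in range(n)],
            columns=[f"{prefix}{j}" for j in range(d)],
        ),
        stage=stage,
    )
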