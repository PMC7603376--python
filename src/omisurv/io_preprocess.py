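"""Reading, preprocessing and cohort partitioning of per-category omics data.

Each omics category (mRNA, miRNA, methylation, CNV, somatic mutation, RPPA)
arrives as a delimited samples x features table. Preprocessing removes
all-zero feature columns, binarizes somatic-mutation calls, and z-scores
every remaining matrix per sample row. Samples present in all categories
and in the clinical table form the "common" cohort; per-category extras are
"uncommon" and serve later as a transfer-validation cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical category order used everywhere downstream (merging, reports).
CATEGORIES = ("mRNA", "miRNA", "methylation", "CNV", "somatic_mutation", "RPPA")

#: Processing stages in order.
STAGES = ("raw", "preprocessed", "compressed", "scaled")


@dataclass
class OmicsMatrix:
    """One omics category's samples x features value table.

    Parameters
    ----------
    category : str
        One of :data:`CATEGORIES`.
    values : pandas.DataFrame
        Real-valued matrix, index = sample ids, columns = feature ids.
    stage : str
        Provenance marker, one of :data:`STAGES`.
    """

    category: str
    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in {self.category}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, sample_ids) -> "OmicsMatrix":
        """Row-subset by sample id, preserving the requested order."""
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise KeyError(f"sample id {missing[0]!r} not in {self.category} matrix")
        return replace(self, values=self.values.loc[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class ClinicalTable:
    """Per-sample follow-up time (days), event indicator and histology label."""

    data: pd.DataFrame  # columns: time_days, event, histology; index: sample_id

    REQUIRED = ("time_days", "event", "histology")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in clinical table")
        if not set(np.unique(self.data["event"])) <= {0, 1}:
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"sample id {missing[0]!r} not in clinical table")
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class CohortPartition:
    """Common ids (present in every category and the clinic) and per-category extras."""

    common_ids: list[str]
    uncommon_ids_by_category: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "common": list(self.common_ids),
            "uncommon": {c: list(v) for c, v in self.uncommon_ids_by_category.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def read_omics_matrix(path, category: str, delimiter: str = "\t") -> OmicsMatrix:
    """Parse a delimited samples x features table into a raw :class:`OmicsMatrix`.

    The first row holds feature ids, the first column sample ids. Duplicate
    feature columns (e.g. one gene measured by two probes) are merged by
    arithmetic mean; duplicate sample ids are rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, header=0)
    df.index = df.index.astype(str)
    # restore duplicate feature names verbatim (pandas mangles them to X.1)
    df.columns = pd.Index([str(c) for c in header[1:]])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"unparseable cell at sample {df.index[r]!r}, feature "
            f"{df.columns[c]!r} in {path}: {df.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at sample {df.index[r]!r}, feature {df.columns[c]!r} in {path}"
        )
    if numeric.columns.has_duplicates:
        numeric = numeric.T.groupby(level=0, sort=False).mean().T
    return OmicsMatrix(category=category, values=numeric.astype(float), stage="raw")


def read_clinical_table(path, delimiter: str = "\t") -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time_days, event, histology."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df[list(ClinicalTable.REQUIRED)])


def filter_followup(
    clinical: ClinicalTable, min_days: float = 1.0, max_days: float = 3650.0
) -> ClinicalTable:
    """Keep records with min_days < follow-up < max_days (both bounds exclusive).

    The defaults drop unfollowed patients (<= 1 day) and follow-up beyond ten
    years (>= 3650 days). Order of the retained records is preserved.
    """
    t = clinical.data["time_days"]
    if t.isna().any():
        raise ValueError("time_days missing for some records")
    keep = (t > min_days) & (t < max_days)
    out = clinical.data.loc[keep]
    if out.empty:
        logger.warning("follow-up filter removed every record")
    return ClinicalTable(out)


def preprocess(matrix: OmicsMatrix) -> OmicsMatrix:
    """Apply the per-category preprocessing rules to a raw matrix.

    (a) all-zero feature columns are removed first; (b) somatic-mutation
    values are binarized (any nonzero call becomes 1) and left unscaled;
    (c) every other category is z-scored per sample row with the population
    standard deviation (denominator n). A constant row cannot be
    standardized and raises, naming the sample.
    """
    if matrix.stage != "raw":
        raise ValueError(f"preprocess expects a raw matrix, got stage {matrix.stage!r}")
    if matrix.shape[1] < 2:
        raise ValueError("matrix must have at least 2 features")
    df = matrix.values
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at sample {df.index[r]!r}, feature {df.columns[c]!r}"
        )
    nonzero = (df != 0).any(axis=0)
    df = df.loc[:, nonzero]
    if matrix.category == "somatic_mutation":
        out = (df != 0).astype(float)
    else:
        arr = df.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, keepdims=True)  # population sd, denominator n
        flat = np.flatnonzero(sd.ravel() == 0)
        if flat.size:
            raise ValueError(
                f"zero-variance row for sample {df.index[flat[0]]!r} "
                f"in {matrix.category}; cannot standardize"
            )
        out = pd.DataFrame((arr - mu) / sd, index=df.index, columns=df.columns)
    return OmicsMatrix(category=matrix.category, values=out, stage="preprocessed")


def partition_cohort(
    matrices: list[OmicsMatrix], clinical: ClinicalTable
) -> CohortPartition:
    """Split sample ids into the common cohort and per-category uncommon sets.

    Common ids are those present in every provided category AND the clinical
    table; per category, uncommon ids are that category's clinical-covered
    ids minus the common set.
    """
    if not matrices:
        raise ValueError("at least one category required")
    clin = set(clinical.sample_ids)
    common = clin.copy()
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("common sample-id set is empty across the provided categories")
    uncommon = {
        m.category: sorted((set(m.sample_ids) & clin) - common) for m in matrices
    }
    return CohortPartition(
        common_ids=sorted(common), uncommon_ids_by_category=uncommon
    )
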