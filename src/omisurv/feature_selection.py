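"""Two-tier survival-association screening of latent features.

Per category, a latent feature is retained if (1) its univariate Cox-PH
score-test p-value is below alpha1 = 0.01, or (2) it falls in
[alpha1, alpha2 = 0.05) and ranks among the top_k = 3 smallest p-values of
that tier within its category. The retained features from all categories
are merged by sample id into the integration matrix that subtype discovery
clusters. No multiple-testing correction is applied (a deliberate property
of the screening rule; see docs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import CATEGORIES, ClinicalTable, OmicsMatrix
from .survival_stats import FeatureSurvivalAssoc, coxph_univariate

logger = logging.getLogger(__name__)


@dataclass
class SelectedFeatureSet:
    """Per-category latent features surviving the two-tier screen."""

    by_category: dict[str, list[FeatureSurvivalAssoc]]
    alpha1: float = 0.01
    alpha2: float = 0.05
    top_k: int = 3
    rule_by_feature: dict[str, int] = field(default_factory=dict)  # 1 or 2

    def feature_ids(self, category: str) -> list[str]:
        return [a.feature_id for a in self.by_category.get(category, [])]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_category.values())

    def counts(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.by_category.items()}

    def to_json(self, path) -> None:
        payload = {
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "top_k": self.top_k,
            "selected": {
                c: [
                    {
                        "feature_id": a.feature_id,
                        "coef": a.coef,
                        "p_value": a.p_value,
                        "rule": self.rule_by_feature.get(a.feature_id),
                    }
                    for a in assocs
                ]
                for c, assocs in self.by_category.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class IntegrationMatrix:
    """Merged matrix of selected latent features across categories."""

    values: pd.DataFrame  # index: common sample ids; columns: latent feature ids
    category_by_column: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def categories(self) -> list[str]:
        seen: list[str] = []
        for col in self.values.columns:
            c = self.category_by_column[col]
            if c not in seen:
                seen.append(c)
        return seen


def screen_category(
    matrix: OmicsMatrix, clinical: ClinicalTable, test: str = "score"
) -> list[FeatureSurvivalAssoc]:
    """Univariate Cox-PH association of every column with survival."""
    clin = clinical.subset(matrix.sample_ids)
    times = clin.data["time_days"].to_numpy(dtype=float)
    events = clin.data["event"].to_numpy(dtype=int)
    out = []
    for fid in matrix.feature_ids:
        x = matrix.values[fid].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.warning("skipping zero-variance feature %s", fid)
            continue
        out.append(
            coxph_univariate(
                x, times, events, category=matrix.category, feature_id=fid, test=test
            )
        )
    return out


def _latent_index(feature_id: str) -> int:
    """Trailing latent index of a feature id, for deterministic tie-breaks."""
    tail = feature_id.rsplit("z", 1)[-1]
    try:
        return int(tail)
    except ValueError:
        return 0


def select_features(
    assocs_by_category: dict[str, list[FeatureSurvivalAssoc]],
    alpha1: float = 0.01,
    alpha2: float = 0.05,
    top_k: int = 3,
) -> SelectedFeatureSet:
    """Apply the two-tier rule per category.

    Rule 1: p < alpha1 (no cap). Rule 2: alpha1 <= p < alpha2, ranked by
    ascending p, at most top_k per category; ties at the boundary break by
    ascending latent index. A category may retain nothing (warning).
    """
    selected: dict[str, list[FeatureSurvivalAssoc]] = {}
    rules: dict[str, int] = {}
    for cat, assocs in assocs_by_category.items():
        ordered = sorted(assocs, key=lambda a: (a.p_value, _latent_index(a.feature_id)))
        tier1 = [a for a in ordered if a.p_value < alpha1]
        tier2 = [a for a in ordered if alpha1 <= a.p_value < alpha2][:top_k]
        keep = tier1 + tier2
        if not keep:
            logger.warning("no features pass the survival screen for %s", cat)
        selected[cat] = keep
        for a in tier1:
            rules[a.feature_id] = 1
        for a in tier2:
            rules[a.feature_id] = 2
    return SelectedFeatureSet(
        by_category=selected, alpha1=alpha1, alpha2=alpha2, top_k=top_k,
        rule_by_feature=rules,
    )


def merge_selected(
    scaled_by_category: dict[str, OmicsMatrix], selection: SelectedFeatureSet
) -> IntegrationMatrix:
    """Concatenate selected columns in canonical category order, rows by sample id."""
    frames = []
    cat_by_col: dict[str, str] = {}
    ref_ids: list[str] | None = None
    for cat in CATEGORIES:
        if cat not in scaled_by_category:
            continue
        fids = selection.feature_ids(cat)
        if not fids:
            continue
        m = scaled_by_category[cat]
        if ref_ids is None:
            ref_ids = sorted(m.sample_ids)
        if sorted(m.sample_ids) != ref_ids:
            raise ValueError(
                f"sample ids of {cat} do not match the other categories"
            )
        frames.append(m.values.loc[ref_ids, fids])
        for f in fids:
            cat_by_col[f] = cat
    if not frames:
        raise ValueError("no category contributed any selected feature")
    return IntegrationMatrix(values=pd.concat(frames, axis=1), category_by_column=cat_by_col)


def slice_category(matrix: IntegrationMatrix, category: str) -> IntegrationMatrix:
    """Columns of one category only, rows unchanged."""
    cols = [c for c in matrix.values.columns if matrix.category_by_column[c] == category]
    if not cols:
        raise KeyError(f"category {category!r} not present in the integration matrix")
    return IntegrationMatrix(
        values=matrix.values[cols],
        category_by_column={c: category for c in cols},
    )
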