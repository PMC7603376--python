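"""Per-category subtype classifiers and label transfer to incomplete-omics samples.

One L2-penalized logistic regression (C = 1.0) per omics category predicts
the integration subtype from that category's selected latent features
alone. Each classifier is scored by the mean test AUC over five fresh,
seeded 80/20 splits, then refit on the full common cohort and applied to
uncommon samples of its category — encoded by the already-trained
autoencoder and scaled by the common-cohort statistics, so no information
flows from the transfer cohort into any fitted artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .io_preprocess import ClinicalTable, OmicsMatrix
from .clustering import SubtypeAssignment
from .feature_selection import IntegrationMatrix
from .survival_stats import SurvivalComparison, chi2_independence, compare_survival, roc_auc

logger = logging.getLogger(__name__)


@dataclass
class CategoryClassifier:
    category: str
    feature_ids: list[str]
    coef: np.ndarray
    intercept: float
    C: float = 1.0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(subtype = 1) for each row of x."""
        z = x @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class RepeatedAUC:
    category: str
    aucs: list[float]
    n_repeats: int = 5
    test_fraction: float = 0.2
    seeds: list[int] | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs))


def _fit_logistic(x, y, C=1.0):
    # L2 penalty (the sklearn default), inverse strength C
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    clf.fit(x, y)
    return clf


def evaluate_category(
    matrix_slice: IntegrationMatrix,
    labels: SubtypeAssignment,
    n_repeats: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
    C: float = 1.0,
):
    """Repeated-split AUC of one category's classifier, plus the final refit.

    For each repeat a fresh seeded 80/20 split is drawn; if a split leaves a
    single class on either side it is redrawn with the next seed (logged).
    The AUC is for the predicted probability of subtype 1 (the
    longer-surviving group). The returned classifier is refit on all data.
    """
    x = matrix_slice.values.to_numpy(dtype=float)
    y = labels.vector(matrix_slice.sample_ids)
    if np.unique(y).size < 2:
        raise ValueError("both subtypes must be present to train a classifier")
    if np.unique(y).size > 2:
        raise ValueError(
            "AUC evaluation is defined for exactly two subtypes; "
            f"got {np.unique(y).size}"
        )
    category = next(iter(matrix_slice.category_by_column.values()))
    aucs, used_seeds = [], []
    split_seed = seed
    for _ in range(n_repeats):
        for _attempt in range(100):
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=test_fraction, random_state=split_seed
            )
            split_seed += 1
            if np.unique(ytr).size == 2 and np.unique(yte).size == 2:
                break
            logger.info(
                "degenerate split for %s (seed %d); redrawing", category, split_seed - 1
            )
        else:
            raise RuntimeError(f"could not draw a two-class split for {category}")
        used_seeds.append(split_seed - 1)
        clf = _fit_logistic(xtr, ytr, C=C)
        p1 = clf.predict_proba(xte)[:, list(clf.classes_).index(1)]
        aucs.append(roc_auc(p1, yte))
    final = _fit_logistic(x, y, C=C)
    idx1 = list(final.classes_).index(1)
    sign = 1.0 if idx1 == 1 else -1.0
    classifier = CategoryClassifier(
        category=category,
        feature_ids=list(matrix_slice.values.columns),
        coef=sign * final.coef_[0],
        intercept=float(sign * final.intercept_[0]),
        C=C,
    )
    return (
        RepeatedAUC(
            category=category, aucs=aucs, n_repeats=n_repeats,
            test_fraction=test_fraction, seeds=used_seeds,
        ),
        classifier,
    )


def transfer_predict(
    classifier: CategoryClassifier, uncommon_scaled: OmicsMatrix
) -> SubtypeAssignment:
    """Predict subtypes for uncommon samples from their scaled latent features.

    Hard labels at probability threshold 0.5; a probability of exactly 0.5
    maps to subtype 1 (documented convention). Probabilities are retained.
    """
    missing = [f for f in classifier.feature_ids if f not in uncommon_scaled.values.columns]
    if missing:
        raise ValueError(
            f"uncommon matrix lacks selected feature {missing[0]!r} "
            f"for {classifier.category}"
        )
    x = uncommon_scaled.values[classifier.feature_ids].to_numpy(dtype=float)
    ids = pd.Index(uncommon_scaled.sample_ids, name="sample_id")
    if x.shape[0] == 0:
        empty = pd.Series([], index=ids, dtype=int)
        return SubtypeAssignment(labels=empty, provenance="predicted",
                                 probabilities=pd.Series([], index=ids, dtype=float))
    p = classifier.predict_proba(x)
    labels = (p >= 0.5).astype(int)
    return SubtypeAssignment(
        labels=pd.Series(labels, index=ids),
        provenance="predicted",
        probabilities=pd.Series(p, index=ids),
    )


@dataclass
class ValidationReport:
    survival: SurvivalComparison
    subtype_counts: dict[int, int]
    histology_chi2: float
    histology_p: float

    def to_json_dict(self) -> dict:
        return {
            "logrank_chi2": self.survival.logrank_chi2,
            "logrank_p": self.survival.p_value,
            "km_medians": {str(k): v for k, v in self.survival.medians.items()},
            "subtype_counts": {str(k): v for k, v in self.subtype_counts.items()},
            "histology_chi2": self.histology_chi2,
            "histology_p": self.histology_p,
        }


def validate_assignment(
    assignment: SubtypeAssignment, clinical: ClinicalTable
) -> ValidationReport:
    """Survival and histology-independence validation of a subtype assignment.

    Kaplan-Meier curves and the log-rank test across subtypes, plus a
    chi-square test of independence between subtype and histology label.
    """
    counts = assignment.counts()
    if len(counts) < 2:
        raise ValueError("assignment contains a single subtype; nothing to compare")
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 samples per subtype")
    clin = clinical.subset(assignment.sample_ids)
    times = clin.data["time_days"].to_numpy(dtype=float)
    events = clin.data["event"].to_numpy(dtype=int)
    labels = assignment.vector()
    surv = compare_survival(times, events, labels)
    ct = pd.crosstab(labels, clin.data["histology"].to_numpy())
    chi2, p = chi2_independence(ct.to_numpy())
    return ValidationReport(
        survival=surv, subtype_counts=counts, histology_chi2=chi2, histology_p=p
    )
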