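"""Subtype attribution on uncompressed protein (RPPA) data.

Two gradient-boosted tree presets predict the integration survival subtype
from the raw (preprocessed, uncompressed) common RPPA matrix and are then
explained with exact path-dependent Shapley values, ranking proteins by
mean absolute attribution. The module also provides the single-omics
baseline mode: the full screening/clustering/transfer pipeline run on one
uncompressed matrix without the autoencoder, for side-by-side comparison
with the multi-omics integration subtypes.

Preset A mirrors an XGBoost-style configuration (learning rate 0.2, depth-3
trees, 0.5 row subsampling) via GradientBoostingClassifier; preset B a
LightGBM-style one (learning rate 0.05, 10 leaves, histogram binning) via
HistGradientBoostingClassifier. scikit-learn caps the histogram at 255 bins
(one bin is reserved for missing values), one below the nominal 256.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, HistGradientBoostingClassifier
from sklearn.model_selection import train_test_split

from .io_preprocess import ClinicalTable, OmicsMatrix
from .clustering import SubtypeAssignment, fit_kmeans, k_selection, order_labels_by_survival
from .compression import ColumnScaler, scale_compressed
from .feature_selection import (
    IntegrationMatrix,
    merge_selected,
    screen_category,
    select_features,
)
from .survival_stats import roc_auc
from .transfer import RepeatedAUC, evaluate_category, transfer_predict, validate_assignment
from .treeshap import (
    flatten_gradient_boosting,
    flatten_hist_gradient_boosting,
    tree_shap_values,
)

logger = logging.getLogger(__name__)

PRESETS = ("xgboost_like", "lightgbm_like")


@dataclass
class GBDTConfig:
    """Gradient-boosted tree settings for the two presets.

    Preset A ("xgboost_like"): learning_rate 0.2, max_depth 3, subsample 0.5.
    Preset B ("lightgbm_like"): learning_rate 0.05, num_leaves 10, max_bins 255.
    ``n_rounds`` boosting iterations, no early stopping (determinism).
    """

    preset: str = "xgboost_like"
    n_rounds: int = 100
    seed: int = 0
    learning_rate_a: float = 0.2
    max_depth_a: int = 3
    subsample_a: float = 0.5
    learning_rate_b: float = 0.05
    num_leaves_b: int = 10
    max_bins_b: int = 255

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")
        if not (0 < self.learning_rate_a <= 1 and 0 < self.learning_rate_b <= 1):
            raise ValueError("learning rates must lie in (0, 1]")
        if not (0 < self.subsample_a <= 1):
            raise ValueError("subsample must lie in (0, 1]")
        if self.max_depth_a <= 0 or self.num_leaves_b <= 1:
            raise ValueError("tree sizes must be positive")

    def build(self, seed: int | None = None):
        seed = self.seed if seed is None else seed
        if self.preset == "xgboost_like":
            return GradientBoostingClassifier(
                learning_rate=self.learning_rate_a,
                max_depth=self.max_depth_a,
                subsample=self.subsample_a,
                n_estimators=self.n_rounds,
                random_state=seed,
            )
        return HistGradientBoostingClassifier(
            learning_rate=self.learning_rate_b,
            max_leaf_nodes=self.num_leaves_b,
            max_bins=self.max_bins_b,
            max_iter=self.n_rounds,
            early_stopping=False,
            random_state=seed,
        )


@dataclass
class AttributionResult:
    """Per-sample Shapley attributions and the derived protein ranking."""

    preset: str
    shap_values: pd.DataFrame  # samples x features
    base_value: float
    margins: np.ndarray  # model raw output per sample

    @property
    def mean_abs(self) -> pd.Series:
        return self.shap_values.abs().mean(axis=0).sort_values(ascending=False)

    def top_features(self, k: int = 5) -> list[str]:
        return list(self.mean_abs.index[:k])

    def local_accuracy_error(self) -> float:
        """Max |base + sum(phi) - margin| over samples; exactness check."""
        recon = self.base_value + self.shap_values.sum(axis=1).to_numpy()
        return float(np.max(np.abs(recon - self.margins)))


def fit_gbdt(
    rppa_common: OmicsMatrix,
    labels: SubtypeAssignment,
    config: GBDTConfig,
    n_repeats: int = 5,
    test_fraction: float = 0.2,
):
    """Fit one GBDT preset on all common RPPA and score it by repeated-split AUC.

    The AUC protocol matches the subtype-transfer stage: five fresh seeded
    80/20 splits, AUC of the predicted probability of subtype 1 on the test
    portion, then a final refit on the full cohort.
    """
    if rppa_common.stage != "preprocessed":
        raise ValueError("fit_gbdt expects the uncompressed preprocessed RPPA matrix")
    x = rppa_common.values.to_numpy(dtype=float)
    y = labels.vector(rppa_common.sample_ids)
    if np.unique(y).size < 2:
        raise ValueError("both subtypes must be present")
    aucs, used_seeds = [], []
    split_seed = config.seed
    for _ in range(n_repeats):
        for _attempt in range(100):
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=test_fraction, random_state=split_seed
            )
            split_seed += 1
            if np.unique(ytr).size == 2 and np.unique(yte).size == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class split")
        used_seeds.append(split_seed - 1)
        model = config.build(seed=split_seed - 1)
        model.fit(xtr, ytr)
        p1 = model.predict_proba(xte)[:, list(model.classes_).index(1)]
        aucs.append(roc_auc(p1, yte))
    final = config.build()
    final.fit(x, y)
    rep = RepeatedAUC(
        category="RPPA", aucs=aucs, n_repeats=n_repeats,
        test_fraction=test_fraction, seeds=used_seeds,
    )
    return final, rep


def shap_attribution(model, rppa_common: OmicsMatrix, preset: str) -> AttributionResult:
    """Exact path-dependent Shapley values of a fitted GBDT on the RPPA matrix."""
    x = rppa_common.values.to_numpy(dtype=float)
    if isinstance(model, GradientBoostingClassifier):
        n_in = model.n_features_in_
    else:
        n_in = model.n_features_in_
    if x.shape[1] != n_in:
        raise ValueError(
            f"feature mismatch: matrix has {x.shape[1]} features, model expects {n_in}"
        )
    if isinstance(model, GradientBoostingClassifier):
        trees, offset = flatten_gradient_boosting(model)
    elif isinstance(model, HistGradientBoostingClassifier):
        trees, offset = flatten_hist_gradient_boosting(model)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    phi, base = tree_shap_values(trees, x)
    margins = np.ravel(model.decision_function(x))
    return AttributionResult(
        preset=preset,
        shap_values=pd.DataFrame(
            phi, index=rppa_common.values.index, columns=rppa_common.values.columns
        ),
        base_value=base + offset,
        margins=margins,
    )


@dataclass
class BaselineReport:
    """Single-omics pipeline results for side-by-side comparison."""

    category: str
    selected_features: list[str]
    chosen_k: int
    assignment: SubtypeAssignment
    common_validation: object
    repeated_auc: RepeatedAUC | None
    transfer_assignment: SubtypeAssignment | None
    uncommon_validation: object | None
    notes: list[str] = field(default_factory=list)


def single_omics_baseline(
    common: OmicsMatrix,
    uncommon: OmicsMatrix | None,
    clinical: ClinicalTable,
    alpha1: float = 0.01,
    alpha2: float = 0.05,
    top_k: int = 3,
    k_range=range(2, 11),
    seed: int = 0,
) -> BaselineReport:
    """The full subtype pipeline on one uncompressed matrix (no autoencoder).

    Raw (preprocessed) features are column-scaled on the common cohort,
    Cox-screened with the same two-tier rule, clustered into survival
    subtypes, classified, and transferred to the uncommon samples with
    Kaplan-Meier validation — the control arm that isolates what the
    multi-omics integration adds.
    """
    notes: list[str] = []
    scaler = ColumnScaler.fit(common)
    common_scaled = scale_compressed(common, scaler)
    assocs = screen_category(common_scaled, clinical)
    selection = select_features(
        {common.category: assocs}, alpha1=alpha1, alpha2=alpha2, top_k=top_k
    )
    n_sel = selection.total
    if n_sel == 0:
        raise ValueError(f"no {common.category} feature passes the survival screen")
    if n_sel < top_k:
        notes.append(f"only {n_sel} features passed screening; proceeding with those")
        logger.warning("%s baseline: only %d features passed screening", common.category, n_sel)
    matrix = merge_selected({common.category: common_scaled}, selection)
    if n_sel == 1:
        chosen_k = 2
        notes.append("single selected feature; skipped k-selection, using K = 2")
    else:
        chosen_k = k_selection(matrix, k_range=k_range, seed=seed).chosen_k
    raw_labels, _, _ = fit_kmeans(matrix, chosen_k, seed=seed)
    assignment = order_labels_by_survival(raw_labels, matrix.sample_ids, clinical)
    common_val = validate_assignment(assignment, clinical)
    rep_auc = classifier = None
    counts = assignment.counts()
    if len(counts) == 2 and min(counts.values()) >= 5:
        rep_auc, classifier = evaluate_category(matrix, assignment, seed=seed)
    else:
        notes.append(
            "clustering did not yield two usable subtypes "
            f"(counts {counts}); classifier and transfer skipped"
        )
        logger.warning(
            "%s baseline: no two usable subtypes, skipping transfer", common.category
        )
    transfer_assign = None
    uncommon_val = None
    if classifier is not None and uncommon is not None and uncommon.shape[0] > 0:
        uncommon_scaled = scale_compressed(uncommon, scaler)
        transfer_assign = transfer_predict(classifier, uncommon_scaled)
        try:
            uncommon_val = validate_assignment(transfer_assign, clinical)
        except ValueError as exc:
            notes.append(f"uncommon validation unavailable: {exc}")
    return BaselineReport(
        category=common.category,
        selected_features=selection.feature_ids(common.category),
        chosen_k=chosen_k,
        assignment=assignment,
        common_validation=common_val,
        repeated_auc=rep_auc,
        transfer_assignment=transfer_assign,
        uncommon_validation=uncommon_val,
        notes=notes,
    )
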