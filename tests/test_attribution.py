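import numpy as np
import pandas as pd
import pytest

from omisurv import (
    GBDTConfig,
    OmicsMatrix,
    PipelineConfig,
    SyntheticConfig,
    filter_followup,
    fit_gbdt,
    generate_cohort,
    partition_cohort,
    preprocess,
    run_pipeline,
    shap_attribution,
    single_omics_baseline,
)
from omisurv.clustering import SubtypeAssignment

from conftest import make_matrix


def _assign(labels, ids):
    return SubtypeAssignment(
        labels=pd.Series(list(labels), index=pd.Index(ids, name="sample_id")),
    )


def _rppa(n=250, d=25, n_inf=4, shift=2.0, seed=0):
    """Small preprocessed-stage RPPA matrix with known informative proteins."""
    rng = np.random.default_rng(seed)
    y = rng.binomial(1, 0.5, n)
    x = rng.standard_normal((n, d))
    x[:, :n_inf] += shift * y[:, None]
    m = make_matrix(x, category="RPPA", stage="preprocessed", prefix="prot")
    return m, y


class TestFitGbdt:
    @pytest.mark.parametrize("preset", ["xgboost_like", "lightgbm_like"])
    def test_strong_signal_high_auc(self, preset):
        m, y = _rppa(seed=1)
        cfg = GBDTConfig(preset=preset, n_rounds=60, seed=0)
        _, rep = fit_gbdt(m, _assign(y, m.sample_ids), cfg)
        assert rep.mean > 0.85
        assert len(rep.aucs) == 5

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(2)
        m, _ = _rppa(n=400, n_inf=0, seed=2)
        y = rng.binomial(1, 0.5, 400)
        cfg = GBDTConfig(n_rounds=60, seed=0)
        _, rep = fit_gbdt(m, _assign(y, m.sample_ids), cfg)
        assert 0.4 <= rep.mean <= 0.6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GBDTConfig(preset="catboost_like")
        with pytest.raises(ValueError):
            GBDTConfig(learning_rate_a=1.5)
        with pytest.raises(ValueError):
            GBDTConfig(subsample_a=0.0)


class TestShapAttribution:
    @pytest.mark.parametrize("preset", ["xgboost_like", "lightgbm_like"])
    def test_local_accuracy_every_sample(self, preset):
        m, y = _rppa(seed=3)
        cfg = GBDTConfig(preset=preset, n_rounds=40, seed=0)
        model, _ = fit_gbdt(m, _assign(y, m.sample_ids), cfg)
        attr = shap_attribution(model, m, preset=preset)
        assert attr.local_accuracy_error() < 1e-4

    def test_informative_proteins_dominate_ranking(self):
        m, y = _rppa(seed=4)
        cfg = GBDTConfig(n_rounds=60, seed=0)
        model, _ = fit_gbdt(m, _assign(y, m.sample_ids), cfg)
        attr = shap_attribution(model, m, preset="xgboost_like")
        top4 = set(attr.top_features(4))
        assert len(top4 & {"prot0", "prot1", "prot2", "prot3"}) >= 3

    def test_constant_feature_gets_zero_attribution(self):
        m, y = _rppa(seed=5)
        vals = m.values.copy()
        vals["prot24"] = 1.0  # never split on -> zero Shapley throughout
        m = OmicsMatrix(category="RPPA", values=vals, stage="preprocessed")
        cfg = GBDTConfig(n_rounds=30, seed=0)
        model, _ = fit_gbdt(m, _assign(y, m.sample_ids), cfg)
        attr = shap_attribution(model, m, preset="xgboost_like")
        np.testing.assert_array_equal(attr.shap_values["prot24"].to_numpy(), 0.0)

    def test_feature_mismatch_errors(self):
        m, y = _rppa(seed=6)
        cfg = GBDTConfig(n_rounds=10, seed=0)
        model, _ = fit_gbdt(m, _assign(y, m.sample_ids), cfg)
        narrower = OmicsMatrix(
            category="RPPA", values=m.values.iloc[:, :10], stage="preprocessed"
        )
        with pytest.raises(ValueError, match="mismatch"):
            shap_attribution(model, narrower, preset="xgboost_like")


def _contrast_cohort(seed):
    """Survival driven by a multi-omics factor; RPPA additionally carries a
    strong survival-independent two-group factor on three decoy proteins."""
    cfg = SyntheticConfig(
        n_common=400,
        n_uncommon_by_category={"RPPA": 250},
        feature_dims={"mRNA": 120, "miRNA": 60, "methylation": 120,
                      "CNV": 60, "somatic_mutation": 60, "RPPA": 150},
        signal_strength={"mRNA": 0.8, "miRNA": 0.0, "methylation": 0.8,
                         "CNV": 0.0, "somatic_mutation": 0.0, "RPPA": 0.5},
        n_informative={"mRNA": 30, "miRNA": 0, "methylation": 30,
                       "CNV": 0, "somatic_mutation": 0, "RPPA": 40},
        hazard_ratio=3.0,
        seed=seed,
    )
    mats, clin, truth = generate_cohort(cfg)
    rng = np.random.default_rng(seed + 10_000)
    rppa = next(m for m in mats if m.category == "RPPA")
    decoys = [c for c in rppa.feature_ids
              if c not in truth.informative_features_by_category["RPPA"]][:3]
    c_factor = rng.binomial(1, 0.5, rppa.shape[0])
    vals = rppa.values.copy()
    for col in decoys:
        vals[col] = vals[col] + 4.0 * c_factor
    mats = [m if m.category != "RPPA"
            else OmicsMatrix(category="RPPA", values=vals, stage="raw")
            for m in mats]
    return mats, clin, truth


class TestSingleOmicsBaseline:
    def test_integration_transfers_better_than_single_omics(self):
        """Distributed multi-omics survival signal: the integrated subtype
        transfers to the uncommon RPPA cohort with a stronger survival split
        than subtypes clustered from raw RPPA alone."""
        mats, clin, truth = _contrast_cohort(seed=27)
        pcfg = PipelineConfig(seed=27, run_attribution=False, run_baseline=False)
        rep = run_pipeline(pcfg, inputs=(mats, clin, truth))
        integration_p = rep["stages"]["transfer"]["RPPA"]["validation"]["logrank_p"]

        clin_f = filter_followup(clin)
        part = partition_cohort(mats, clin_f)
        rppa = next(m for m in mats if m.category == "RPPA")
        keep = set(part.common_ids) | set(part.uncommon_ids_by_category["RPPA"])
        pre = preprocess(rppa.subset([i for i in rppa.sample_ids if i in keep]))
        base = single_omics_baseline(
            pre.subset(part.common_ids),
            pre.subset(part.uncommon_ids_by_category["RPPA"]),
            clin_f,
            seed=27,
        )
        assert base.uncommon_validation is not None
        baseline_p = base.uncommon_validation.survival.p_value
        assert integration_p < 0.05
        assert baseline_p > 0.05
        assert integration_p < baseline_p

    def test_identical_single_category_signal_both_arms_succeed(self, tiny_cohort):
        # strong RPPA signal: direct RPPA subtyping works on its own
        matrices, clinical, _ = tiny_cohort
        clin_f = filter_followup(clinical)
        part = partition_cohort(matrices, clin_f)
        rppa = next(m for m in matrices if m.category == "RPPA")
        keep = set(part.common_ids) | set(part.uncommon_ids_by_category["RPPA"])
        pre = preprocess(rppa.subset([i for i in rppa.sample_ids if i in keep]))
        base = single_omics_baseline(
            pre.subset(part.common_ids),
            pre.subset(part.uncommon_ids_by_category["RPPA"]),
            clin_f,
            seed=0,
        )
        assert base.chosen_k == 2
        assert base.common_validation.survival.p_value < 0.01
        assert base.repeated_auc.mean > 0.9

    def test_scarce_screen_survivors_still_proceed(self):
        # survival tied to a single protein: fewer than top_k may pass
        rng = np.random.default_rng(8)
        n = 150
        risk = rng.standard_normal(n)
        t = np.maximum(1.5, rng.exponential(400 * np.exp(-1.2 * risk)))
        e = (rng.random(n) < 0.8).astype(int)
        x = rng.standard_normal((n, 5))
        x[:, 0] = risk
        m = make_matrix(x, category="RPPA", stage="preprocessed", prefix="prot")
        import pandas as pd
        from omisurv import ClinicalTable

        clin = ClinicalTable(
            pd.DataFrame(
                {"time_days": t, "event": e, "histology": ["LUAD"] * n},
                index=pd.Index(m.sample_ids, name="sample_id"),
            )
        )
        base = single_omics_baseline(m, None, clin, seed=1)
        assert "prot0" in base.selected_features
        assert len(base.selected_features) < 3
        assert base.chosen_k >= 2
        # the pipeline degrades gracefully rather than erroring
        if base.chosen_k != 2:
            assert base.repeated_auc is None
            assert any("subtypes" in n for n in base.notes)
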