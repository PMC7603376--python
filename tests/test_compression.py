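import numpy as np
import pandas as pd
import pytest

from omisurv import (
    ColumnScaler,
    CompressorConfig,
    OmicsMatrix,
    TrainedCompressor,
    encode,
    scale_compressed,
    train_compressor,
)

from conftest import make_matrix


def _standardized(rng, n, d):
    x = rng.standard_normal((n, d))
    x = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
    return x


@pytest.fixture(scope="module")
def trained_small():
    """Small miRNA-like matrix (width 217) trained briefly."""
    rng = np.random.default_rng(0)
    m = make_matrix(_standardized(rng, 60, 217), category="miRNA", stage="preprocessed")
    cfg = CompressorConfig(epochs=15, seed=1)
    return m, train_compressor(m, cfg)


class TestTrainCompressor:
    def test_bottleneck_width_100(self, trained_small):
        m, comp = trained_small
        z = encode(comp, m)
        assert z.shape == (60, 100)
        assert z.stage == "compressed"
        assert z.feature_ids[0] == "miRNA_z1"
        assert z.feature_ids[-1] == "miRNA_z100"

    def test_history_covers_every_epoch(self, trained_small):
        _, comp = trained_small
        assert len(comp.history["train_loss"]) == comp.config.epochs
        assert len(comp.history["val_loss"]) == comp.config.epochs
        assert np.all(np.isfinite(comp.history["train_loss"]))
        assert np.all(np.isfinite(comp.history["val_loss"]))

    def test_training_reduces_loss_on_structured_data(self):
        # rank-1 data: reconstruction is learnable, loss must fall
        rng = np.random.default_rng(2)
        u = rng.standard_normal((200, 1))
        v = rng.standard_normal((1, 120))
        m = make_matrix(u @ v, category="mRNA", stage="preprocessed")
        comp = train_compressor(m, CompressorConfig(epochs=30, seed=3))
        assert comp.history["train_loss"][-1] < comp.history["train_loss"][0]

    def test_reconstruction_beats_input_variance_on_low_rank_data(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((150, 2)) @ rng.standard_normal((2, 80))
        m = make_matrix(x, category="RPPA", stage="preprocessed")
        comp = train_compressor(m, CompressorConfig(epochs=60, seed=5))
        from omisurv.compression import _forward_eval

        _, _, _, recon = _forward_eval(comp.weights, x.astype(np.float32))
        mse = float(np.mean((recon - x) ** 2))
        assert mse < float(np.var(x))

    def test_too_few_samples_errors(self):
        m = make_matrix(np.random.default_rng(0).standard_normal((5, 20)),
                        stage="preprocessed")
        with pytest.raises(ValueError, match="at least 10"):
            train_compressor(m, CompressorConfig(epochs=1))

    def test_narrow_input_warns_but_trains(self, caplog):
        rng = np.random.default_rng(6)
        m = make_matrix(_standardized(rng, 20, 12), stage="preprocessed")
        with caplog.at_level("WARNING"):
            comp = train_compressor(m, CompressorConfig(epochs=2, seed=0))
        assert "below the bottleneck" in caplog.text
        assert encode(comp, m).shape == (20, 100)


class TestEncode:
    def test_deterministic_repeat_encoding(self, trained_small):
        m, comp = trained_small
        a = encode(comp, m).values.to_numpy()
        b = encode(comp, m).values.to_numpy()
        assert (a == b).all()

    def test_new_samples_encode_without_retraining(self, trained_small):
        _, comp = trained_small
        rng = np.random.default_rng(9)
        fresh = OmicsMatrix(
            category="miRNA",
            values=pd.DataFrame(
                _standardized(rng, 7, 217),
                index=[f"U{i}" for i in range(7)],
                columns=comp.feature_ids,
            ),
            stage="preprocessed",
        )
        assert encode(comp, fresh).shape == (7, 100)

    def test_feature_mismatch_reports_first_difference(self, trained_small):
        m, comp = trained_small
        wrong = OmicsMatrix(
            category="miRNA",
            values=m.values.rename(columns={"f3": "extra"}),
            stage="preprocessed",
        )
        with pytest.raises(ValueError, match="position 3"):
            encode(comp, wrong)

    def test_extra_column_rejected(self, trained_small):
        m, comp = trained_small
        wider = OmicsMatrix(
            category="miRNA",
            values=m.values.assign(extra=0.0),
            stage="preprocessed",
        )
        with pytest.raises(ValueError, match="218"):
            encode(comp, wider)


class TestRoundTrip:
    def test_save_load_preserves_encoding(self, trained_small, tmp_path):
        m, comp = trained_small
        comp.save(tmp_path / "ckpt")
        loaded = TrainedCompressor.load(tmp_path / "ckpt")
        a = encode(comp, m).values.to_numpy()
        b = encode(loaded, m).values.to_numpy()
        assert (a == b).all()


class TestColumnScaling:
    def _compressed(self, values, category="miRNA"):
        n, d = np.asarray(values).shape
        return OmicsMatrix(
            category=category,
            values=pd.DataFrame(
                np.asarray(values, dtype=float),
                index=[f"S{i}" for i in range(n)],
                columns=[f"{category}_z{j + 1}" for j in range(d)],
            ),
            stage="compressed",
        )

    def test_self_scaling_gives_unit_columns(self):
        rng = np.random.default_rng(0)
        m = self._compressed(rng.standard_normal((50, 4)) * 3 + 1)
        out = scale_compressed(m, ColumnScaler.fit(m))
        arr = out.values.to_numpy()
        np.testing.assert_allclose(arr.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(arr.std(0), 1.0, atol=1e-12)
        assert out.stage == "scaled"

    def test_uncommon_scaled_by_common_statistics(self):
        common = self._compressed([[0.0], [4.0]])  # mean 2, sd 2
        scaler = ColumnScaler.fit(common)
        unc = self._compressed([[4.0]])
        out = scale_compressed(unc, scaler)
        assert out.values.iloc[0, 0] == pytest.approx(1.0)

    def test_constant_column_passes_through_as_zeros(self, caplog):
        m = self._compressed([[1.0, 2.0], [1.0, 3.0]])
        with caplog.at_level("WARNING"):
            scaler = ColumnScaler.fit(m)
        assert "constant latent column" in caplog.text
        out = scale_compressed(m, scaler)
        np.testing.assert_array_equal(out.values.iloc[:, 0].to_numpy(), [0.0, 0.0])
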