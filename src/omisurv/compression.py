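"""Per-category autoencoder compression to a 100-dimensional latent space.

Architecture: dense 500 (tanh) -> dropout 0.5 -> dense 100 (tanh,
bottleneck) -> dropout 0.5 -> dense 500 (tanh) -> linear output of input
width. The three hidden dense layers carry an L2 penalty (0.001) on their
kernel weights and an L1 penalty (0.0001) on their activations. Training is
plain stochastic gradient descent (lr 0.01, per-update decay
lr0 / (1 + decay * t), mean-squared-error loss, 150 epochs) on a seeded
80/20 train/validation split of the common cohort; uncommon samples are
never trained on, only encoded.

Implemented directly in numpy (forward + backprop) so the package has no
deep-learning framework dependency; float32 internally for CPU speed, with
deterministic, dropout-free encoding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class CompressorConfig:
    layer_widths: tuple[int, int, int] = (500, 100, 500)
    dropout_rate: float = 0.5
    kernel_l2: float = 0.001
    activity_l1: float = 0.0001
    learning_rate: float = 0.01
    decay: float = 1e-6
    epochs: int = 150
    batch_size: int = 32
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_widths) != 3:
            raise ValueError("layer_widths must name the three hidden layers")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for name in ("kernel_l2", "activity_l1", "learning_rate", "decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must lie in (0, 1]")

    @property
    def bottleneck(self) -> int:
        return self.layer_widths[1]


@dataclass
class TrainedCompressor:
    """Fitted autoencoder for one omics category."""

    category: str
    config: CompressorConfig
    feature_ids: list[str]
    weights: list[np.ndarray]  # W1, b1, W2, b2, W3, b3, W4, b4
    history: dict[str, list[float]]  # train_loss, val_loss per epoch

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", *self.weights)
        meta = {
            "category": self.category,
            "config": asdict(self.config),
            "feature_ids": self.feature_ids,
            "history": self.history,
        }
        (directory / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "TrainedCompressor":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        with np.load(directory / "weights.npz") as z:
            weights = [z[k] for k in z.files]
        cfg = meta["config"]
        cfg["layer_widths"] = tuple(cfg["layer_widths"])
        return cls(
            category=meta["category"],
            config=CompressorConfig(**cfg),
            feature_ids=meta["feature_ids"],
            weights=weights,
            history=meta["history"],
        )


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


def _forward_eval(weights, x):
    """Deterministic forward pass, dropout disabled. Returns all activations."""
    w1, b1, w2, b2, w3, b3, w4, b4 = weights
    h1 = np.tanh(x @ w1 + b1)
    h2 = np.tanh(h1 @ w2 + b2)
    h3 = np.tanh(h2 @ w3 + b3)
    out = h3 @ w4 + b4
    return h1, h2, h3, out


def train_compressor(
    matrix: OmicsMatrix, config: CompressorConfig | None = None
) -> TrainedCompressor:
    """Train the autoencoder on a preprocessed common-cohort matrix."""
    config = config or CompressorConfig()
    if matrix.stage != "preprocessed":
        raise ValueError("train_compressor expects a preprocessed matrix")
    x_all = matrix.values.to_numpy(dtype=np.float32)
    n, d = x_all.shape
    if n < 10:
        raise ValueError("need at least 10 samples to train a compressor")
    if np.isnan(x_all).any():
        raise ValueError("matrix contains missing values")
    if d < config.bottleneck:
        logger.warning(
            "%s input width %d is below the bottleneck width %d; "
            "compression cannot reduce dimension", matrix.category, d, config.bottleneck
        )

    rng = np.random.default_rng(config.seed)
    h1w, h2w, h3w = config.layer_widths
    weights = [
        _glorot(rng, d, h1w), np.zeros(h1w, np.float32),
        _glorot(rng, h1w, h2w), np.zeros(h2w, np.float32),
        _glorot(rng, h2w, h3w), np.zeros(h3w, np.float32),
        _glorot(rng, h3w, d), np.zeros(d, np.float32),
    ]

    perm = rng.permutation(n)
    n_train = max(1, int(round(config.train_fraction * n)))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    x_train, x_val = x_all[train_idx], x_all[val_idx]

    l2 = np.float32(config.kernel_l2)
    l1 = np.float32(config.activity_l1)
    p_drop = config.dropout_rate
    keep = np.float32(1.0 - p_drop)
    step = 0  # global update counter for the lr decay
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        batch_losses = []
        for start in range(0, n_train, config.batch_size):
            xb = x_train[order[start : start + config.batch_size]]
            b = xb.shape[0]
            w1, b1, w2, b2, w3, b3, w4, b4 = weights

            h1 = np.tanh(xb @ w1 + b1)
            m1 = (rng.random(h1.shape) >= p_drop).astype(np.float32) / keep
            h1d = h1 * m1
            h2 = np.tanh(h1d @ w2 + b2)
            m2 = (rng.random(h2.shape) >= p_drop).astype(np.float32) / keep
            h2d = h2 * m2
            h3 = np.tanh(h2d @ w3 + b3)
            out = h3 @ w4 + b4

            resid = out - xb
            mse = float(np.mean(resid.astype(np.float64) ** 2))
            reg = config.kernel_l2 * sum(
                float(np.sum(w.astype(np.float64) ** 2)) for w in (w1, w2, w3)
            ) + config.activity_l1 * (
                float(np.sum(np.abs(h1))) + float(np.sum(np.abs(h2)))
                + float(np.sum(np.abs(h3)))
            ) / b
            loss = mse + reg
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"({matrix.category})"
                )
            batch_losses.append(loss)

            # backprop (MSE averaged over batch * features)
            d_out = (2.0 / (b * d)) * resid
            g_w4 = h3.T @ d_out
            g_b4 = d_out.sum(axis=0)
            d_h3 = d_out @ w4.T + (l1 / b) * np.sign(h3)
            d_p3 = d_h3 * (1.0 - h3 * h3)
            g_w3 = h2d.T @ d_p3 + 2.0 * l2 * w3
            g_b3 = d_p3.sum(axis=0)
            d_h2 = (d_p3 @ w3.T) * m2 + (l1 / b) * np.sign(h2)
            d_p2 = d_h2 * (1.0 - h2 * h2)
            g_w2 = h1d.T @ d_p2 + 2.0 * l2 * w2
            g_b2 = d_p2.sum(axis=0)
            d_h1 = (d_p2 @ w2.T) * m1 + (l1 / b) * np.sign(h1)
            d_p1 = d_h1 * (1.0 - h1 * h1)
            g_w1 = xb.T @ d_p1 + 2.0 * l2 * w1
            g_b1 = d_p1.sum(axis=0)

            lr = np.float32(config.learning_rate / (1.0 + config.decay * step))
            step += 1
            grads = [g_w1, g_b1, g_w2, g_b2, g_w3, g_b3, g_w4, g_b4]
            for w, g in zip(weights, grads):
                w -= lr * g

        history["train_loss"].append(float(np.mean(batch_losses)))
        if x_val.size:
            _, _, _, out_v = _forward_eval(weights, x_val)
            val_mse = float(np.mean((out_v.astype(np.float64) - x_val) ** 2))
        else:
            val_mse = float("nan")
        history["val_loss"].append(val_mse)

    return TrainedCompressor(
        category=matrix.category,
        config=config,
        feature_ids=list(matrix.feature_ids),
        weights=weights,
        history=history,
    )


def encode(compressor: TrainedCompressor, matrix: OmicsMatrix) -> OmicsMatrix:
    """Deterministic forward pass to the bottleneck (dropout disabled).

    The matrix must present exactly the compressor's training features in
    the same order; latent columns are labelled ``<category>_z1..z100``.
    """
    if matrix.stage != "preprocessed":
        raise ValueError("encode expects a preprocessed matrix")
    if list(matrix.feature_ids) != list(compressor.feature_ids):
        got, want = list(matrix.feature_ids), list(compressor.feature_ids)
        if len(got) != len(want):
            raise ValueError(
                f"feature-id mismatch: matrix has {len(got)} features, "
                f"compressor expects {len(want)}"
            )
        i = next(k for k, (a, b) in enumerate(zip(got, want)) if a != b)
        raise ValueError(
            f"feature-id mismatch at position {i}: matrix has {got[i]!r}, "
            f"compressor expects {want[i]!r}"
        )
    x = matrix.values.to_numpy(dtype=np.float32)
    w1, b1, w2, b2, *_ = compressor.weights
    z = np.tanh(np.tanh(x @ w1 + b1) @ w2 + b2).astype(np.float64)
    cols = [f"{compressor.category}_z{i + 1}" for i in range(z.shape[1])]
    df = pd.DataFrame(z, index=matrix.values.index, columns=cols)
    return OmicsMatrix(category=compressor.category, values=df, stage="compressed")


@dataclass
class ColumnScaler:
    """Column-wise z-scoring statistics fitted on the common compressed matrix."""

    category: str
    feature_ids: list[str]
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, matrix: OmicsMatrix) -> "ColumnScaler":
        # fitted on the common cohort; compressed latents in the integration
        # path, preprocessed raw features in the single-omics baseline
        if matrix.stage not in ("compressed", "preprocessed"):
            raise ValueError("ColumnScaler fits on a compressed or preprocessed matrix")
        arr = matrix.values.to_numpy(dtype=float)
        means = arr.mean(axis=0)
        sds = arr.std(axis=0)
        if np.any(sds == 0):
            j = int(np.flatnonzero(sds == 0)[0])
            logger.warning(
                "constant latent column %s in %s; it will scale to zeros",
                matrix.feature_ids[j], matrix.category,
            )
        return cls(
            category=matrix.category,
            feature_ids=list(matrix.feature_ids),
            means=means,
            sds=sds,
        )


def scale_compressed(matrix: OmicsMatrix, reference: ColumnScaler) -> OmicsMatrix:
    """Column-wise z-score using reference (common-cohort) statistics.

    Uncommon matrices are scaled with the COMMON-cohort means/sds — the
    scaler is a fitted artifact and is never refit on transfer data.
    Zero-variance reference columns pass through as zeros.
    """
    if matrix.stage not in ("compressed", "preprocessed"):
        raise ValueError("scale_compressed expects a compressed or preprocessed matrix")
    if list(matrix.feature_ids) != list(reference.feature_ids):
        raise ValueError("feature ids do not match the scaler's reference")
    arr = matrix.values.to_numpy(dtype=float)
    sds = np.where(reference.sds == 0, 1.0, reference.sds)
    scaled = (arr - reference.means) / sds
    scaled[:, reference.sds == 0] = 0.0
    df = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.feature_ids)
    return OmicsMatrix(category=matrix.category, values=df, stage="scaled")
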