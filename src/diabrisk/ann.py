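"""Minimal feed-forward neural-network regressor, the comparison arm to the
seven regression patterns.

One hidden tanh layer, linear output, full-batch gradient descent on squared
error. Inputs and targets are standardised internally; predictions are
returned on the raw risk-percent scale. Initialisation is fully determined by
the seed, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .evidence import DoseResponseDataset

__all__ = ["AnnConfig", "AnnModel", "train_ann", "predict_ann"]


@dataclass(frozen=True)
class AnnConfig:
    hidden_units: int = 8
    learning_rate: float = 0.05
    epochs: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not (self.learning_rate > 0 and np.isfinite(self.learning_rate)):
            raise ValueError("learning_rate must be positive and finite")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class AnnModel:
    """Trained single-hidden-layer network and its standardisation constants."""

    w1: np.ndarray  # (1, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: float
    x_std: float
    y_mean: float
    y_std: float
    config: AnnConfig
    training_r_squared: float

    def predict(self, factor_value: float | np.ndarray) -> float | np.ndarray:
        return predict_ann(self, factor_value)

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean,
            "x_std": self.x_std,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "config": asdict(self.config),
            "training_r_squared": self.training_r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        return cls(
            w1=np.asarray(d["w1"], float),
            b1=np.asarray(d["b1"], float),
            w2=np.asarray(d["w2"], float),
            b2=float(d["b2"]),
            x_mean=float(d["x_mean"]),
            x_std=float(d["x_std"]),
            y_mean=float(d["y_mean"]),
            y_std=float(d["y_std"]),
            config=AnnConfig(**d["config"]),
            training_r_squared=float(d["training_r_squared"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _forward(w1, b1, w2, b2, xs: np.ndarray):
    h = np.tanh(xs[:, None] * w1 + b1)  # (n, hidden)
    return h, h @ w2 + b2


def train_ann(dataset: DoseResponseDataset, config: AnnConfig) -> AnnModel:
    """Train the network on one dose-response dataset.

    Raises if the squared-error loss goes non-finite (divergence), with a
    hint to lower the learning rate.
    """
    x, y = dataset.x, dataset.y
    if x.size < 4:
        raise ValueError("ANN training needs at least 4 points")
    x_mean, x_std = float(x.mean()), float(x.std())
    y_mean, y_std = float(y.mean()), float(y.std())
    x_std = x_std or 1.0
    y_std = y_std or 1.0
    xs = (x - x_mean) / x_std
    ys = (y - y_mean) / y_std
    n = xs.size

    rng = np.random.default_rng(config.seed)
    h = config.hidden_units
    w1 = rng.normal(scale=1.0, size=(1, h))[0]
    b1 = rng.normal(scale=0.1, size=h)
    w2 = rng.normal(scale=1.0 / np.sqrt(h), size=h)
    b2 = 0.0
    lr = config.learning_rate

    for _ in range(config.epochs):
        hid, out = _forward(w1, b1, w2, b2, xs)
        err = out - ys
        with np.errstate(over="ignore"):
            loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise ValueError(
                "training diverged (non-finite loss); try a smaller learning rate"
            )
        g_out = 2.0 * err / n  # (n,)
        g_w2 = hid.T @ g_out
        g_b2 = float(g_out.sum())
        g_hid = g_out[:, None] * w2 * (1.0 - hid**2)  # (n, h)
        g_w1 = xs @ g_hid
        g_b1 = g_hid.sum(axis=0)
        w1 = w1 - lr * g_w1
        b1 = b1 - lr * g_b1
        w2 = w2 - lr * g_w2
        b2 = b2 - lr * g_b2

    _, out = _forward(w1, b1, w2, b2, xs)
    pred = out * y_std + y_mean
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return AnnModel(
        w1=w1[None, :] if w1.ndim == 1 else w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        config=config,
        training_r_squared=r2,
    )


def predict_ann(model: AnnModel, factor_value: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the network on the raw risk-percent scale."""
    x = np.atleast_1d(np.asarray(factor_value, dtype=float))
    xs = (x - model.x_mean) / model.x_std
    w1 = model.w1[0] if model.w1.ndim == 2 else model.w1
    _, out = _forward(w1, model.b1, model.w2, model.b2, xs)
    pred = out * model.y_std + model.y_mean
    if np.ndim(factor_value) == 0:
        return float(pred[0])
    return pred
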