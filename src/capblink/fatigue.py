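"""Fatigue self-assessment scoring and the 3-5-1 blink-feature regressor.

The ground-truth fatigue label is the Fatigue Self-Assessment Scale (FSAS):
ten statements each rated 1 (never) to 5 (always), summed to a total between
10 (least fatigued) and 50 (most fatigued).

A small feed-forward network maps the three blink features of a 40 s window
-- mean eye closing time, mean eye opening time, mean idle (inter-blink)
time, all in seconds -- to that scale. The architecture is fixed at 3 inputs,
5 sigmoid hidden units, 1 linear output, trained by full-batch
backpropagation on mean-squared error; features are z-scored and the target
is mapped to [0, 1] internally, and predictions are clamped back to the
questionnaire range.

Accuracy is reported as 100% minus the mean absolute relative error between
predicted and self-assessed scales.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FSASForm",
    "score_fsas",
    "FatigueSample",
    "TrainConfig",
    "FatigueNetwork",
    "train",
    "predict",
    "predict_many",
    "accuracy",
    "train_test_split",
]

SCALE_MIN = 10.0
SCALE_MAX = 50.0

N_INPUT, N_HIDDEN, N_OUTPUT = 3, 5, 1


@dataclass(frozen=True)
class FSASForm:
    """Ten questionnaire responses, each an integer rating in 1-5."""

    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        responses = tuple(int(r) for r in self.responses)
        object.__setattr__(self, "responses", responses)
        if len(responses) != 10:
            raise ValueError(f"FSAS form needs 10 responses, got {len(responses)}")
        for i, r in enumerate(responses, start=1):
            if not 1 <= r <= 5:
                raise ValueError(f"response {i} out of range 1-5: {r}")


def score_fsas(form: FSASForm | Sequence[int], reverse_items: bool = False) -> int:
    """Total FSAS score, the plain sum of the ten responses (range 10-50).

    The questionnaire assigns 1-5 uniformly to every statement and the total
    is the simple sum, including the positively-worded items; pass
    ``reverse_items=True`` to apply the psychometric convention of reverse
    scoring items 4 and 10 instead.
    """
    if not isinstance(form, FSASForm):
        form = FSASForm(tuple(form))
    responses = list(form.responses)
    if reverse_items:
        for idx in (3, 9):
            responses[idx] = 6 - responses[idx]
    return int(sum(responses))


@dataclass(frozen=True)
class FatigueSample:
    """One training example: blink features (s) and the FSAS total."""

    closing: float
    opening: float
    idle: float
    scale: float

    def __post_init__(self) -> None:
        for name in ("closing", "opening", "idle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not SCALE_MIN <= self.scale <= SCALE_MAX:
            raise ValueError(f"scale must be in [{SCALE_MIN}, {SCALE_MAX}], got {self.scale}")

    @property
    def features(self) -> tuple[float, float, float]:
        return (self.closing, self.opening, self.idle)


@dataclass(frozen=True)
class TrainConfig:
    """Backpropagation settings.

    iterations: full-batch gradient steps; the loss curve flattens out by
    ~1500 on the synthetic task. learning_rate applies in the normalized
    feature/target space. train_fraction is the share used for fitting when
    a split is requested.
    """

    iterations: int = 2000
    learning_rate: float = 0.5
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class FatigueNetwork:
    """Weights and normalization state of the 3-5-1 regressor."""

    w1: np.ndarray  # (3, 5)
    b1: np.ndarray  # (5,)
    w2: np.ndarray  # (5,)
    b2: float
    feature_mean: np.ndarray  # (3,)
    feature_std: np.ndarray  # (3,)
    seed: int = 0
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    trained: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "architecture": [N_INPUT, N_HIDDEN, N_OUTPUT],
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "seed": self.seed,
            "trained": self.trained,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FatigueNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        if payload.get("architecture") != [N_INPUT, N_HIDDEN, N_OUTPUT]:
            raise ValueError(f"unsupported architecture {payload.get('architecture')}")
        return cls(
            w1=np.asarray(payload["w1"], dtype=float),
            b1=np.asarray(payload["b1"], dtype=float),
            w2=np.asarray(payload["w2"], dtype=float),
            b2=float(payload["b2"]),
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_std=np.asarray(payload["feature_std"], dtype=float),
            seed=int(payload.get("seed", 0)),
            trained=bool(payload.get("trained", False)),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _samples_to_arrays(samples: Sequence[FatigueSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([s.features for s in samples], dtype=float)
    y = np.array([s.scale for s in samples], dtype=float)
    return x, y


def train(samples: Sequence[FatigueSample], cfg: TrainConfig | None = None) -> FatigueNetwork:
    """Fit the 3-5-1 network by full-batch gradient descent on MSE.

    Deterministic for a fixed seed and sample multiset (sample order does not
    matter because gradients are full-batch sums). Returns the network with
    its per-iteration loss trajectory (MSE in normalized target units).
    """
    cfg = cfg or TrainConfig()
    if len(samples) < 10:
        raise ValueError(f"need at least 10 samples to train, got {len(samples)}")
    x, y = _samples_to_arrays(samples)

    mean = x.mean(axis=0)
    std = x.std(axis=0)
    degenerate = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if degenerate.any():
        warnings.warn("constant feature(s) detected; standardization skipped for them")
        std = np.where(degenerate, 1.0, std)
    xn = (x - mean) / std
    yn = (y - SCALE_MIN) / (SCALE_MAX - SCALE_MIN)  # target in [0, 1]

    rng = np.random.default_rng(cfg.seed)
    w1 = rng.normal(0.0, 0.5, size=(N_INPUT, N_HIDDEN))
    b1 = np.zeros(N_HIDDEN)
    w2 = rng.normal(0.0, 0.5, size=N_HIDDEN)
    b2 = 0.0

    n = len(samples)
    losses = np.empty(cfg.iterations)
    lr = cfg.learning_rate
    for it in range(cfg.iterations):
        h = _sigmoid(xn @ w1 + b1)  # (n, 5)
        out = h @ w2 + b2  # (n,)
        err = out - yn
        losses[it] = float(np.mean(err**2))

        g_out = 2.0 * err / n  # dL/dout
        g_w2 = h.T @ g_out
        g_b2 = g_out.sum()
        g_h = np.outer(g_out, w2) * h * (1.0 - h)  # (n, 5)
        g_w1 = xn.T @ g_h
        g_b1 = g_h.sum(axis=0)

        w1 -= lr * g_w1
        b1 -= lr * g_b1
        w2 -= lr * g_w2
        b2 -= lr * g_b2

    return FatigueNetwork(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        feature_mean=mean,
        feature_std=std,
        seed=cfg.seed,
        loss_history=losses,
        trained=True,
    )


def predict_many(net: FatigueNetwork, features: np.ndarray) -> np.ndarray:
    """Forward pass for an (n, 3) feature array; outputs clamped to [10, 50]."""
    if not net.trained:
        raise ValueError("network has not been trained")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    xn = (features - net.feature_mean) / net.feature_std
    h = _sigmoid(xn @ net.w1 + net.b1)
    out = h @ net.w2 + net.b2
    scale = SCALE_MIN + (SCALE_MAX - SCALE_MIN) * out
    return np.clip(scale, SCALE_MIN, SCALE_MAX)


def predict(net: FatigueNetwork, features: Sequence[float]) -> float:
    """Fatigue scale for one (closing, opening, idle) triple."""
    return float(predict_many(net, np.asarray(features, dtype=float))[0])


def accuracy(
    predictions: Sequence[float], truths: Sequence[float], signed: bool = False
) -> float:
    """Relative-error accuracy in percent.

    ``r = (1 - mean(|pred_i - truth_i| / truth_i)) * 100``. With
    ``signed=True`` the absolute value is dropped, letting over- and
    under-predictions cancel. Can be negative for very poor predictors.
    """
    preds = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if preds.shape != truth.shape or preds.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    if np.any(truth <= 0):
        raise ValueError("truth scales must be positive")
    err = (preds - truth) / truth
    if not signed:
        err = np.abs(err)
    return float((1.0 - err.mean()) * 100.0)


def train_test_split(
    samples: Sequence[FatigueSample], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[FatigueSample], list[FatigueSample]]:
    """Seeded random shuffle split into (train, test) lists."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(train_fraction * len(samples)))
    train_set = [samples[i] for i in order[:n_train]]
    test_set = [samples[i] for i in order[n_train:]]
    return train_set, test_set
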