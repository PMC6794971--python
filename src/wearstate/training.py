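"""Training regimes: randomized 70/20/10 split and leave-one-subject-out CV.

Type I draws a uniform random 70/20/10 train/validation/test partition of
all samples.  Type II (leave-one-subject-out) holds one subject's samples
out entirely as the test set and splits the remaining pool 80/20 into
train/validation at random; iterating over subjects gives the 15-fold CV
of the source cohort.  Fractional split sizes round half-up for train and
validation with the remainder going to the test set.

Training minimizes categorical cross-entropy with a selectable optimizer
(Adam by default, with the published tuned hyperparameters) and is fully
reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvalReport, classification_report, confusion_matrix
from .io import FeatureDataset
from .network import ModelSpec
from .nn import MultichannelCNN, make_optimizer

__all__ = [
    "SplitPlan",
    "OptimizerConfig",
    "TrainedModel",
    "split_type1",
    "split_type2",
    "categorical_cross_entropy",
    "train_model",
    "compare_optimizers",
]


@dataclass
class SplitPlan:
    """Disjoint train/validation/test index sets over a sample pool."""

    regime: str
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int
    held_out_subject: str | None = None

    def validate(self, n_samples: int | None = None) -> None:
        parts = [self.train, self.val, self.test]
        total = sum(map(len, parts))
        union = np.union1d(np.union1d(self.train, self.val), self.test)
        if len(union) != total:
            raise ValueError("split members overlap")
        if n_samples is not None and (total != n_samples or (len(union) and union[-1] >= n_samples)):
            raise ValueError(f"split covers {total} of {n_samples} samples")


@dataclass
class OptimizerConfig:
    """Optimizer choice plus the published tuned hyperparameters as defaults.

    ``beta_1``/``beta_2`` apply to Adam only (the search tuned Adam);
    RMSprop and SGD use the learning rate and decay alone.
    """

    name: str = "adam"
    learning_rate: float = 0.00125
    beta_1: float = 0.9765841
    beta_2: float = 0.8541287
    decay: float = 0.000235
    epochs: int = 100
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.name not in ("adam", "rmsprop", "sgd"):
            raise ValueError(f"unknown optimizer {self.name!r}")
        if self.learning_rate < 0 or self.decay < 0:
            raise ValueError("rates must be non-negative")
        if not (0 < self.beta_1 < 1 and 0 < self.beta_2 < 1):
            raise ValueError("betas must lie in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_type1(n_samples: int, seed: int = 0) -> SplitPlan:
    """Uniform random 70/20/10 split of ``n_samples`` indices."""
    if n_samples < 10:
        raise ValueError("need at least 10 samples for a 70/20/10 split")
    n_train = _round_half_up(0.7 * n_samples)
    n_val = _round_half_up(0.2 * n_samples)
    perm = np.random.default_rng(seed).permutation(n_samples)
    return SplitPlan("type1", np.sort(perm[:n_train]),
                     np.sort(perm[n_train:n_train + n_val]),
                     np.sort(perm[n_train + n_val:]), seed)


def split_type2(ds: FeatureDataset, held_out_subject: str, seed: int = 0) -> SplitPlan:
    """Leave-one-subject-out fold: subject -> test; rest 80/20 train/val."""
    mask = ds.subject_ids == held_out_subject
    if not mask.any():
        raise ValueError(f"unknown subject {held_out_subject!r}")
    test = np.flatnonzero(mask)
    rest = np.flatnonzero(~mask)
    if len(rest) == 0:
        raise ValueError("cohort of one subject leaves an empty training pool")
    perm = np.random.default_rng(seed).permutation(len(rest))
    n_train = _round_half_up(0.8 * len(rest))
    return SplitPlan("type2", np.sort(rest[perm[:n_train]]),
                     np.sort(rest[perm[n_train:]]), test, seed,
                     held_out_subject=held_out_subject)


def categorical_cross_entropy(y_true: np.ndarray, y_pred: np.ndarray,
                              eps: float = 1e-12) -> float:
    """Mean negative log predicted probability of the true class.

    ``y_true`` is one-hot (n, 5); ``y_pred`` rows must sum to 1 within
    1e-6.  Zero predicted probability at a true class is clipped at
    ``eps`` rather than raising.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must share a shape")
    if not np.allclose(y_pred.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("prediction rows must sum to 1")
    if not np.array_equal(y_true.sum(axis=1), np.ones(len(y_true))) or not np.isin(y_true, (0.0, 1.0)).all():
        raise ValueError("y_true must be one-hot")
    p = np.clip((y_true * y_pred).sum(axis=1), eps, 1.0)
    return float(-np.mean(np.log(p))) + 0.0  # normalize -0.0


def _one_hot(labels: np.ndarray, n_classes: int = 5) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _split_blocks(X: np.ndarray, channels: dict[str, int]) -> dict[str, np.ndarray]:
    out, start = {}, 0
    for ch, width in channels.items():
        out[ch] = X[:, start:start + width]
        start += width
    return out


@dataclass
class TrainedModel:
    """A fitted network plus its training history and feature scaler."""

    net: MultichannelCNN
    history: pd.DataFrame
    config: OptimizerConfig
    seed: int
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None

    def _prepare(self, X: np.ndarray) -> dict[str, np.ndarray]:
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_std
        return _split_blocks(X, self.net.spec.channel_features)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._prepare(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, ds: FeatureDataset, indices: np.ndarray) -> EvalReport:
        pred = self.predict(ds.features[indices])
        return classification_report(confusion_matrix(ds.labels[indices], pred))


def train_model(
    spec: ModelSpec,
    ds: FeatureDataset,
    plan: SplitPlan,
    opt: OptimizerConfig | None = None,
    seed: int = 0,
    standardize: bool = True,
    class_weight: bool = False,
) -> TrainedModel:
    """Minibatch-train the network on the plan's training split.

    Features are standardized with the training split's mean/sd by default
    (raw feature scales span several orders of magnitude).  The returned
    history has one row per epoch with train/val loss and accuracy, both
    evaluated in inference mode (dropout off).  Identical (seed, config)
    produce bit-identical histories.  ``class_weight=True`` weights each
    sample inversely to its class frequency in the training split; the
    default leaves the published imbalance untouched.
    """
    opt = opt or OptimizerConfig()
    for part in (plan.train, plan.val):
        if len(part) == 0:
            raise ValueError("empty split member")
    X = ds.features.copy()
    if standardize:
        mu = X[plan.train].mean(axis=0)
        sd = X[plan.train].std(axis=0)
        sd[sd < 1e-12] = 1.0
        X = (X - mu) / sd
    else:
        mu = sd = None
    channels = spec.channel_features
    rng = np.random.default_rng(seed)
    net = MultichannelCNN(spec, seed=rng)
    optimizer = make_optimizer(opt.name, opt.learning_rate, opt.beta_1, opt.beta_2, opt.decay)

    y = ds.labels
    w = None
    if class_weight:
        freq = np.bincount(y[plan.train], minlength=5).astype(float)
        freq[freq == 0] = 1.0
        w_class = len(plan.train) / (5 * freq)
        w = w_class[y]

    def eval_split(idx: np.ndarray) -> tuple[float, float]:
        probs = net.forward(_split_blocks(X[idx], channels), train=False)[0]
        loss = categorical_cross_entropy(_one_hot(y[idx]), probs)
        acc = float((probs.argmax(axis=1) == y[idx]).mean())
        return loss, acc

    rows = []
    for epoch in range(opt.epochs):
        order = rng.permutation(len(plan.train))
        for lo in range(0, len(order), opt.batch_size):
            idx = plan.train[order[lo:lo + opt.batch_size]]
            yb = _one_hot(y[idx])
            probs, cache = net.forward(_split_blocks(X[idx], channels), train=True)
            if not np.isfinite(probs).all():
                raise RuntimeError(
                    f"NaN/inf in predictions at epoch {epoch}; lr={opt.learning_rate}, "
                    f"optimizer={opt.name} — aborting")
            if w is not None:
                grads = _weighted_backward(net, cache, yb, w[idx][:, None])
            else:
                grads = net.backward(cache, yb)
            optimizer.step(net.params, grads)
        tr_loss, tr_acc = eval_split(plan.train)
        va_loss, va_acc = eval_split(plan.val)
        if not np.isfinite(tr_loss) or not np.isfinite(va_loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}; aborting")
        rows.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": va_loss,
                     "train_acc": tr_acc, "val_acc": va_acc})
    history = pd.DataFrame(rows)
    return TrainedModel(net, history, opt, seed, mu, sd)


def _weighted_backward(net: MultichannelCNN, cache: dict, yb: np.ndarray,
                       wb: np.ndarray) -> dict[str, np.ndarray]:
    """Backward pass with per-sample weights folded into the CE residual."""
    n = len(yb)
    orig = cache["probs"]
    # (p - y) scaled per sample, renormalized so weights average to 1
    scaled = yb + (orig - yb) * (wb * n / wb.sum())
    cache["probs"] = scaled
    grads = net.backward(cache, yb)
    cache["probs"] = orig
    return grads


def compare_optimizers(
    spec: ModelSpec,
    ds: FeatureDataset,
    plan: SplitPlan,
    configs: list[OptimizerConfig],
    seed: int = 0,
) -> pd.DataFrame:
    """Train once per optimizer config on identical splits; report test metrics.

    Returns one row block per optimizer: accuracy plus per-class precision,
    recall and F1 on the plan's test split.
    """
    if len(configs) == 0:
        raise ValueError("need at least one optimizer config")
    rows = []
    for cfg in configs:
        model = train_model(spec, ds, plan, cfg, seed=seed)
        report = model.evaluate(ds, plan.test)
        row = {"optimizer": cfg.name, "accuracy": report.accuracy}
        for c, name in enumerate(report.class_names):
            row[f"recall_{name}"] = report.recall[c]
            row[f"precision_{name}"] = report.precision[c]
            row[f"f1_{name}"] = report.f1[c]
        rows.append(row)
    return pd.DataFrame(rows)
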