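"""Confusion metrics, ROC/AUROC with bootstrap confidence intervals, the
prediction-horizon sweep, and a fixed gated-recurrent baseline classifier."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import nn
from .childmodel import TrainConfig


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise MetricError("labels and predictions must have equal length")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise MetricError("labels and predictions must be binary")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise MetricError("sensitivity undefined: no positives")
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    denom = counts.tn + counts.fp
    if denom == 0:
        raise MetricError("specificity undefined: no negatives")
    return counts.tn / denom


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outscores random negative), ties counting one half.

    Computed from midranks (Mann-Whitney U), which equals the trapezoidal
    area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUROC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Ordered (FPR, TPR) pairs of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    n_pos = max(int(np.sum(labels == 1)), 1)
    n_neg = max(int(np.sum(labels == 0)), 1)
    tps = np.cumsum(labels == 1)
    fps = np.cumsum(labels == 0)
    # keep only the last point of each tied-score block
    distinct = np.r_[np.diff(scores) != 0, True]
    points = np.column_stack([fps[distinct] / n_neg, tps[distinct] / n_pos])
    return np.vstack([[0.0, 0.0], points])


@dataclass
class RocResult:
    points: np.ndarray
    auroc: float
    ci_lower: float
    ci_upper: float
    replicates: int
    seed: int
    sensitivity: float | None = None
    specificity: float | None = None


def auroc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    replicates: int = 2000,
    seed: int = 0,
    max_retries: int = 100,
) -> RocResult:
    """Percentile bootstrap over episodes (2.5/97.5 percentiles).

    Degenerate resamples (a single class) are redrawn, with capped retries.
    """
    if replicates < 100:
        raise MetricError("replicates must be >= 100")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    point = auroc(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    stats = np.empty(replicates)
    for r in range(replicates):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() != lab.max():
                stats[r] = auroc(scores[idx], lab)
                break
        else:
            raise MetricError("could not draw a two-class bootstrap resample")
    lower, upper = np.percentile(stats, [2.5, 97.5])
    return RocResult(
        points=roc_curve(scores, labels),
        auroc=point,
        ci_lower=float(min(lower, point)),
        ci_upper=float(max(upper, point)),
        replicates=replicates,
        seed=seed,
    )


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    replicates: int = 2000,
    seed: int = 0,
) -> RocResult:
    """AUROC with CI plus sensitivity/specificity at a decision threshold."""
    result = auroc_ci(scores, labels, replicates=replicates, seed=seed)
    counts = confusion_counts(labels, (np.asarray(scores) >= threshold).astype(int))
    result.sensitivity = sensitivity(counts)
    result.specificity = specificity(counts)
    return result


# ---------------------------------------------------------------------------
# fixed-architecture gated recurrent baseline
# ---------------------------------------------------------------------------


@dataclass
class GruBaseline:
    """Single-layer gated recurrent classifier (comparison anchor)."""

    hidden: int
    n_features: int
    params: dict[str, nn.Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, n_features: int, hidden: int, seed: int) -> "GruBaseline":
        rng = np.random.default_rng(seed)

        def mat(rows: int, cols: int) -> nn.Tensor:
            std = np.sqrt(2.0 / (rows + cols))
            return nn.Tensor(rng.normal(0.0, std, size=(rows, cols)), requires_grad=True)

        params = {}
        for gate in ("z", "r", "h"):
            params[f"W{gate}"] = mat(n_features, hidden)
            params[f"U{gate}"] = mat(hidden, hidden)
            params[f"b{gate}"] = nn.Tensor(np.zeros(hidden), requires_grad=True)
        params["Wout"] = mat(hidden, 2)
        params["bout"] = nn.Tensor(np.zeros(2), requires_grad=True)
        return cls(hidden=hidden, n_features=n_features, params=params)

    def parameters(self) -> list[nn.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def forward(self, x: np.ndarray) -> nn.Tensor:
        x = np.asarray(x, dtype=np.float64)
        batch, steps, _ = x.shape
        p = self.params
        h = nn.Tensor(np.zeros((batch, self.hidden)))
        one = nn.Tensor(np.ones((batch, self.hidden)))
        for t in range(steps):
            xt = nn.Tensor(x[:, t, :])
            z = nn.sigmoid(nn.add(nn.add(nn.matmul(xt, p["Wz"]), nn.matmul(h, p["Uz"])), p["bz"]))
            r = nn.sigmoid(nn.add(nn.add(nn.matmul(xt, p["Wr"]), nn.matmul(h, p["Ur"])), p["br"]))
            hh = nn.tanh(
                nn.add(nn.add(nn.matmul(xt, p["Wh"]), nn.matmul(nn.mul(r, h), p["Uh"])), p["bh"])
            )
            h = nn.add(nn.mul(nn.add(one, nn.scale(z, -1.0)), h), nn.mul(z, hh))
        return nn.add(nn.matmul(h, p["Wout"]), p["bout"])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x).data)[:, 1]


def baseline_recurrent(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    train_config: TrainConfig,
    replicates: int = 500,
) -> RocResult:
    """Train the gated baseline with the same regime and score it on test."""
    from .childmodel import train_child  # same early-stopping loop

    model = GruBaseline.init(
        n_features=train_x.shape[2], hidden=train_config.hidden, seed=train_config.seed
    )
    train_child(model, train_x, train_y, val_x, val_y, train_config)
    scores = model.predict_proba(test_x)
    return evaluate_scores(scores, test_y, replicates=replicates, seed=train_config.seed)


def horizon_sweep(*args, **kwargs):
    """Run the full pipeline per horizon; see :func:`nasga.pipeline.horizon_sweep`."""
    from .pipeline import horizon_sweep as _sweep

    return _sweep(*args, **kwargs)
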