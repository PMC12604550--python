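"""A deliberately simple SWS predictor: smooth-then-threshold.

One fitted parameter per epoch (the initial value A, the decay constant,
or their ratio) is smoothed with a moving average and compared with a
threshold.  The threshold, smoothing width, and decision direction are
trained by minimizing misclassification error on held-out-session folds
(leave-one-session-out), and significance is assessed against a
label-shuffle null.  The point of the model is its simplicity: if a
single spatial-fit parameter predicts slow-wave sleep, the spatial
structure carries the state information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdModel",
    "smooth_series",
    "predict",
    "train_loo",
    "shuffle_null",
    "accuracy_precision",
]


@dataclass(frozen=True)
class ThresholdModel:
    threshold: float
    smooth_w: int  # odd moving-average width in epochs
    direction: str  # 'above' or 'below': which side maps to SWS
    param: str = "A"

    def __post_init__(self):
        if self.smooth_w < 1 or self.smooth_w % 2 == 0:
            raise ValueError("smooth_w must be an odd positive integer")
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")


def smooth_series(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average; edges use a shrinking window."""
    x = np.asarray(x, float)
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def predict(series: np.ndarray, model: ThresholdModel) -> np.ndarray:
    """Per-epoch SWS (True) / not-SWS (False) labels."""
    s = smooth_series(series, model.smooth_w)
    return s >= model.threshold if model.direction == "above" else s <= model.threshold


def _error(series, labels, model) -> float:
    return float(np.mean(predict(series, model) != np.asarray(labels, bool)))


def train_loo(
    sessions: list[tuple[np.ndarray, np.ndarray]],
    smooth_grid: tuple[int, ...] = (1, 3, 5, 7, 9),
    n_thresholds: int = 50,
    param: str = "A",
) -> list[ThresholdModel]:
    """Leave-one-session-out training of the threshold model.

    ``sessions`` holds (parameter series, boolean SWS labels) pairs.
    For each held-out session the (smoothing, threshold, direction)
    triple minimizing the mean misclassification error over the
    remaining sessions is selected; the threshold grid is ``n_thresholds``
    quantiles of the pooled training parameter.  Ties break toward
    smaller smoothing, then smaller threshold, then 'above'.
    Returns one model per fold (same order as ``sessions``).
    """
    if len(sessions) < 2:
        raise ValueError("leave-one-out needs at least 2 sessions")
    models = []
    for held in range(len(sessions)):
        train = [s for i, s in enumerate(sessions) if i != held]
        pooled = np.concatenate([s[0] for s in train])
        q = np.quantile(pooled, np.linspace(0, 1, n_thresholds))
        # midpoints of adjacent quantiles guarantee a candidate inside
        # any gap the quantile sequence straddles (separable data)
        thresholds = np.unique(np.concatenate([q, (q[:-1] + q[1:]) / 2]))
        best = None
        for w in smooth_grid:
            for t in thresholds:
                for direction in ("above", "below"):
                    m = ThresholdModel(float(t), w, direction, param)
                    err = float(
                        np.mean([_error(x, y, m) for x, y in train])
                    )
                    key = (err, w, t, direction)
                    if best is None or key < best[0]:
                        best = (key, m)
        models.append(best[1])
    return models


def shuffle_null(
    series: np.ndarray,
    labels: np.ndarray,
    model: ThresholdModel,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Label-shuffle null distribution of the prediction error.

    Labels are permuted uniformly per shuffle and the error recomputed
    against the fixed predictions.  Returns the observed error, the null
    errors, their mean, the central 95% interval, and the rank-based
    empirical p-value (fraction of null errors <= observed).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    labels = np.asarray(labels, bool)
    rng = np.random.default_rng(seed)
    pred = predict(series, model)
    observed = float(np.mean(pred != labels))
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = np.mean(pred != rng.permutation(labels))
    lo, hi = np.percentile(null, [2.5, 97.5])
    return {
        "observed_error": observed,
        "null_errors": null,
        "null_mean": float(null.mean()),
        "null_ci95": (float(lo), float(hi)),
        "p_value": float((np.sum(null <= observed) + 1) / (n_shuffles + 1)),
    }


def accuracy_precision(pred, truth) -> dict:
    """Confusion counts with accuracy and precision.

    accuracy = (TP + TN)/n; precision = TP/(TP + FP), reported as None
    when no positive predictions exist.
    """
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    n = len(pred)
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "accuracy": (tp + tn) / n,
        "precision": tp / (tp + fp) if (tp + fp) > 0 else None,
    }
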