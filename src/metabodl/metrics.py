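"""Losses and evaluation metrics for classification and reconstruction.

Classification is scored with micro-averaged multi-class accuracy and
precision (pooled confusion counts).  Reconstruction similarity uses a
deliberately heterogeneous panel spanning three metric classes:

* divergence/correlation — cosine similarity, Pearson's R;
* distance — Euclidean, Manhattan, Jeffreys–Matusita, logarithmic;
* magnitude — percent difference.

The Jeffreys–Matusita distance ``sqrt(sum (sqrt(x)-sqrt(y))^2)`` and the
logarithmic distance ``sum |log((x+eps)/(y+eps))|`` are defined on
non-negative vectors; when either input contains negatives (fold-change
transformed data lies in [-1, 1]) both vectors are shifted by the pairwise
minimum before scoring.

Latent losses are the closed-form KL divergences to the standard-normal
and uniform-categorical priors used by the (J)VAE training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricReport",
    "classification_metrics",
    "reconstruction_loss",
    "similarity_metrics",
    "latent_kl",
    "latent_kl_categorical",
    "SIMILARITY_METRICS",
]

EPSILON = 1e-9

SIMILARITY_METRICS = (
    "CosineSimilarity", "PearsonsR", "EuclideanDist", "ManhattanDist",
    "JeffreysAndMatusitaDist", "LogarithmicDist", "PercentDifference",
)


@dataclass
class MetricReport:
    """Named scalar results for one model/split."""

    values: dict[str, float] = field(default_factory=dict)
    split: str = ""

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_rows(self, **extra) -> list[dict]:
        """Tidy rows (one per metric) for CSV serialization."""
        return [dict(extra, split=self.split, metric=k, value=v) for k, v in self.values.items()]


def classification_metrics(true_labels, predicted_labels, split: str = "") -> MetricReport:
    """Micro-averaged multi-class accuracy and precision.

    Both are computed from the pooled confusion counts; for single-label
    multi-class problems the two coincide (every false positive for one
    class is a false negative for another).
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.unique(np.concatenate([t, p]))
    tp = sum(int(np.sum((t == c) & (p == c))) for c in classes)
    fp = sum(int(np.sum((t != c) & (p == c))) for c in classes)
    fn = sum(int(np.sum((t == c) & (p != c))) for c in classes)
    # pooled counts: each prediction contributes one TP, or one FP + one FN
    acc = tp / t.size
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    assert tp + fn == t.size
    return MetricReport(values={"AccuracyMCMicro": acc, "PrecisionMCMicro": prec}, split=split)


def reconstruction_loss(pred, target, kind: str = "MSE") -> float:
    """MSE, MAE or MAPE (in percent) between prediction and target."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("pred and target must have equal shapes")
    if kind == "MSE":
        return float(np.mean((p - t) ** 2))
    if kind == "MAE":
        return float(np.mean(np.abs(p - t)))
    if kind == "MAPE":
        return float(np.mean(np.abs(p - t) / (np.abs(t) + EPSILON)) * 100.0)
    raise ValueError(f"unknown loss kind {kind!r}")


def _shift_nonneg(x: np.ndarray, y: np.ndarray):
    lo = min(x.min(), y.min())
    if lo < 0:
        return x - lo, y - lo
    return x, y


def similarity_metrics(x, y, split: str = "") -> MetricReport:
    """The seven-score similarity panel between two equal-length vectors.

    ``y`` is the reference for the percent difference.  Cosine and Pearson
    are reported as NaN (undefined) rather than raising when a norm or
    variance vanishes.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")

    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    cosine = float(x @ y / (nx * ny)) if nx > 0 and ny > 0 else float("nan")

    xc, yc = x - x.mean(), y - y.mean()
    nxc, nyc = np.linalg.norm(xc), np.linalg.norm(yc)
    pearson = float(xc @ yc / (nxc * nyc)) if nxc > 0 and nyc > 0 else float("nan")

    euclid = float(np.linalg.norm(x - y))
    manhattan = float(np.abs(x - y).sum())

    xs, ys = _shift_nonneg(x, y)
    jm = float(np.sqrt(np.sum((np.sqrt(xs) - np.sqrt(ys)) ** 2)))
    logd = float(np.abs(np.log((xs + EPSILON) / (ys + EPSILON))).sum())

    pdiff = float(np.mean(np.abs(x - y) / (np.abs(y) + EPSILON)) * 100.0)

    return MetricReport(
        values={
            "CosineSimilarity": cosine,
            "PearsonsR": pearson,
            "EuclideanDist": euclid,
            "ManhattanDist": manhattan,
            "JeffreysAndMatusitaDist": jm,
            "LogarithmicDist": logd,
            "PercentDifference": pdiff,
        },
        split=split,
    )


def mean_similarity_report(X, Y, split: str = "") -> MetricReport:
    """Per-sample similarity panel averaged across the rows of a split."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    reports = [similarity_metrics(X[i], Y[i]).values for i in range(X.shape[0])]
    keys = reports[0].keys()
    return MetricReport(
        values={k: float(np.nanmean([r[k] for r in reports])) for k in keys}, split=split
    )


def latent_kl(mu, logvar) -> float:
    """KL( N(mu, exp(logvar)) || N(0, 1) ), summed over dimensions."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    return float(-0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar)))


def latent_kl_categorical(logits, n_categories: int | None = None) -> float:
    """KL( softmax(logits) || Uniform(K) ), summed over the last axis."""
    z = np.asarray(logits, dtype=float)
    k = n_categories if n_categories is not None else z.shape[-1]
    z = z - z.max(axis=-1, keepdims=True)
    q = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    return float(np.sum(q * (np.log(q + 1e-30) + np.log(k))))
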