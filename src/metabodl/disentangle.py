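"""Latent-space traversal and disentanglement scoring.

A trained (J)VAE is probed by decoding systematic latent traversals:

* continuous nodes — 16 values at the standard-normal quantiles of 16
  evenly spaced probabilities from 0.05 to 0.95 (the central 90% of the
  prior), all other nodes held at 0;
* discrete nodes — the one-hot vectors, all other nodes held at 0.

Each decoded point is assigned the class label of its nearest reference
sample (Euclidean or percent-difference distance, lexicographic
tie-break).  The number of unique labels assigned across the discrete
nodes summarizes how much class information the discrete latent captured:
with as many discrete nodes as classes, a perfectly disentangled network
scores the number of classes, while a collapsed one scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .metrics import EPSILON

__all__ = [
    "continuous_traversal_grid",
    "discrete_traversal",
    "TraversalResult",
    "traverse_latents",
    "assign_labels",
    "count_unique_labels",
    "unique_label_summary",
]


def continuous_traversal_grid(n_points: int = 16) -> np.ndarray:
    """Standard-normal quantiles of ``n_points`` even steps on [0.05, 0.95]."""
    return norm.ppf(np.linspace(0.05, 0.95, n_points))


def discrete_traversal(n_discrete: int) -> np.ndarray:
    """The ``n`` one-hot vectors of dimension ``n``."""
    if n_discrete < 1:
        raise ValueError("need at least one discrete node")
    return np.eye(n_discrete)


@dataclass
class TraversalResult:
    node: int
    kind: str  # "continuous" | "discrete"
    points: np.ndarray        # latent values traversed (per point)
    latents: np.ndarray       # full latent vectors fed to the decoder
    decoded: np.ndarray       # reconstructions (n_points, n_features)
    assigned_labels: list[str] | None = None
    assigned_distances: np.ndarray | None = None


def traverse_latents(model, kind: str, node: int) -> TraversalResult:
    """Decode a traversal of one latent node, all other nodes held at 0."""
    nC, nD = model.latent.n_continuous, model.latent.n_discrete
    n_latent = nC + nD
    if kind == "continuous":
        if not 0 <= node < nC:
            raise ValueError(f"continuous node {node} out of range")
        grid = continuous_traversal_grid()
        Z = np.zeros((len(grid), n_latent))
        Z[:, node] = grid
        points = grid
    elif kind == "discrete":
        if not 0 <= node < nD:
            raise ValueError(f"discrete node {node} out of range")
        # one-hot on this node only: a single decoder probe per node
        Z = np.zeros((1, n_latent))
        Z[0, nC + node] = 1.0
        points = np.array([1.0])
    else:
        raise ValueError("kind must be 'continuous' or 'discrete'")
    return TraversalResult(node=node, kind=kind, points=points, latents=Z, decoded=model.decode(Z))


def _distances(decoded: np.ndarray, reference: np.ndarray, metric: str) -> np.ndarray:
    d = decoded[:, None, :] - reference[None, :, :]
    if metric == "EuclideanDist":
        return np.sqrt((d**2).sum(axis=-1))
    if metric == "PercentDifference":
        return (np.abs(d) / (np.abs(reference[None, :, :]) + EPSILON)).mean(axis=-1) * 100.0
    raise ValueError("metric must be 'EuclideanDist' or 'PercentDifference'")


def assign_labels(
    traversal: TraversalResult,
    reference: np.ndarray,
    reference_labels,
    metric: str = "EuclideanDist",
) -> TraversalResult:
    """Assign each decoded traversal point its nearest reference label.

    Ties on distance break to the lexicographically smallest label so the
    assignment is deterministic.
    """
    reference = np.asarray(reference, dtype=float)
    labels = [str(l) for l in reference_labels]
    if reference.shape[0] == 0 or reference.shape[0] != len(labels):
        raise ValueError("reference set must be nonempty and labeled")
    dist = _distances(traversal.decoded, reference, metric)
    # sort reference by label so argmin on ties lands on the smallest label
    order = np.argsort(np.asarray(labels, dtype=object), kind="stable")
    dist = dist[:, order]
    labels_sorted = [labels[i] for i in order]
    best = np.argmin(dist, axis=1)
    traversal.assigned_labels = [labels_sorted[i] for i in best]
    traversal.assigned_distances = dist[np.arange(len(best)), best]
    return traversal


def count_unique_labels(assignments) -> int:
    """Number of distinct labels over per-discrete-node assignments."""
    return len(set(assignments))


def discrete_node_labels(
    model, reference: np.ndarray, reference_labels, metric: str = "EuclideanDist"
) -> list[str]:
    """One nearest-reference label per discrete node of the model."""
    out = []
    for node in range(model.latent.n_discrete):
        tr = traverse_latents(model, "discrete", node)
        assign_labels(tr, reference, reference_labels, metric=metric)
        out.append(tr.assigned_labels[0])
    return out


def unique_label_summary(counts_by_run: dict[tuple, list[int]]):
    """Mean +/- SD of unique-label counts over replicate networks.

    ``counts_by_run`` maps a (dataset, split, loss-kind, ...) key to the
    per-replicate unique-label counts; the result is a tidy DataFrame with
    one row per key — the machine twin of a per-condition summary table.
    """
    import pandas as pd

    rows = []
    for key, counts in counts_by_run.items():
        arr = np.asarray(counts, dtype=float)
        rows.append({
            "condition": " / ".join(str(k) for k in key),
            "n_replicates": arr.size,
            "mean_unique_labels": float(arr.mean()),
            "sd_unique_labels": float(arr.std()),
        })
    return pd.DataFrame(rows)
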