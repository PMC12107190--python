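"""Phase-space stratification of predictability.

K-means partitions the attractor into regions; averaging the time-lagged
recurrence index within each region over a horizon grid gives per-region
predictability curves, summarised by their area under the curve (AUC).
Histograms over all reference states locate the typical predictability at a
given horizon (the distribution mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .indices import AlphaField
from .trajectory import Trajectory

__all__ = [
    "ClusterSummary", "kmeans_clusters", "cluster_alpha_curves", "curve_auc",
    "alpha_distribution", "lobe_switching_cluster",
]


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster predictability curves over a horizon grid.

    ``curves[c, j]`` is the mean alpha of cluster ``c`` at horizon ``j``;
    ``auc`` its trapezoidal integral over ``horizon_axis`` (Lyapunov-time
    units when available, else steps) and ``auc_normalized`` the same
    divided by the axis span, so a perfectly predictable cluster scores 1.
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    horizon_axis: np.ndarray
    curves: np.ndarray
    auc: np.ndarray
    auc_normalized: np.ndarray
    counts: np.ndarray


def kmeans_clusters(traj_or_states, k: int, seed: int = 0,
                    n_init: int = 10) -> Tuple[np.ndarray, np.ndarray]:
    """K-means partition of phase-space states (Lloyd + k-means++ restarts).

    Returns per-state labels in ``[0, k)`` and the ``k x D`` centroid
    matrix; the best of ``n_init`` seeded restarts by within-cluster sum of
    squares. Deterministic given ``seed``.
    """
    X = traj_or_states.states if isinstance(traj_or_states, Trajectory) \
        else np.asarray(traj_or_states, dtype=float)
    if k < 1:
        raise ValueError(f"k must be >= 1; got {k}")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of states {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels.astype(np.int64), km.cluster_centers_


def cluster_alpha_curves(field: AlphaField, labels: np.ndarray,
                         centroids: Optional[np.ndarray] = None
                         ) -> ClusterSummary:
    """Mean alpha curve and AUC per cluster.

    ``labels`` may cover every trajectory state (indexed by ``field.refs``)
    or just the field's references, one label each.  Every cluster must
    contain at least one sampled reference.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == field.refs.size:
        ref_labels = labels
    elif labels.size > int(field.refs.max()):
        ref_labels = labels[field.refs]
    else:
        raise ValueError(
            f"labels length {labels.size} matches neither the trajectory "
            f"nor the {field.refs.size} references")
    k = int(ref_labels.max()) + 1
    axis = field.horizon_axis()
    curves = np.empty((k, axis.size))
    counts = np.empty(k, dtype=np.int64)
    for c in range(k):
        sel = ref_labels == c
        counts[c] = int(sel.sum())
        if counts[c] == 0:
            raise ValueError(f"cluster {c} has no sampled reference states")
        curves[c] = field.alpha[sel].mean(axis=0)
    if axis.size >= 2:
        auc = np.array([curve_auc(axis, curves[c]) for c in range(k)])
    else:
        auc = np.full(k, np.nan)  # a single horizon spans no area
    span = float(axis[-1] - axis[0]) if axis.size > 1 else 1.0
    if centroids is None:
        centroids = np.full((k, 1), np.nan)
    return ClusterSummary(k=k, labels=ref_labels, centroids=centroids,
                          horizon_axis=axis, curves=curves, auc=auc,
                          auc_normalized=auc / span if span > 0 else auc,
                          counts=counts)


def curve_auc(horizon_axis: Sequence[float], curve: Sequence[float]) -> float:
    """Trapezoidal area under a predictability curve."""
    x = np.asarray(horizon_axis, dtype=float)
    y = np.asarray(curve, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least two horizons for an area")
    if not np.all(np.diff(x) > 0):
        raise ValueError("horizon axis must be strictly increasing")
    return float(np.trapezoid(y, x))


def alpha_distribution(field: AlphaField, horizon_index: int,
                       bin_width: float = 0.05
                       ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Histogram of alpha over [0, 1] at one horizon, and the mode.

    Returns (counts, bin_edges, mode) where the mode is the centre of the
    most populated bin (ties resolved toward the lower bin).
    """
    if not 0.0 < bin_width <= 1.0:
        raise ValueError(f"bin_width must be in (0, 1]; got {bin_width}")
    vals = field.alpha[:, horizon_index]
    if vals.size == 0:
        raise ValueError("empty alpha column")
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], 1.0)
    counts, edges = np.histogram(vals, bins=edges)
    i = int(np.argmax(counts))
    mode = float(0.5 * (edges[i] + edges[i + 1]))
    return counts, edges, mode


def lobe_switching_cluster(centroids: np.ndarray) -> int:
    """Index of the centroid nearest the mixing region between the two wings.

    For the Lorenz-63 attractor the lobe-switching region sits near
    ``x = y = 0``; cluster numbering from K-means is arbitrary, so the
    cluster is identified geometrically as the centroid minimising
    ``|x| + |y|``.
    """
    c = np.asarray(centroids, dtype=float)
    return int(np.argmin(np.abs(c[:, 0]) + np.abs(c[:, 1])))
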