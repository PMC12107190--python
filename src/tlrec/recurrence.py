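"""Recurrence sets from quantile thresholds on negative-log distances.

For a reference state ``zeta = x(i_ref)`` the observable
``g[t] = -log dist(x(t), zeta)`` is large when the trajectory is close to
the reference.  Recurrences are the states whose ``g`` exceeds a high
quantile threshold ``s(q, zeta)``, after removing a Theiler window of
temporal neighbours (points of the same trajectory pass, which would
otherwise count as spurious recurrences).

Selection is rank-based: with a candidate pool of size ``M`` the recurrence
count is fixed at ``m = max(1, floor((1 - q) * M))`` and the ``m`` largest
``g`` values are taken, ties broken by smaller time index.  A fixed count —
rather than an interpolated quantile — makes the number of recurrences of a
reference state and of its time-shifted image exactly equal, which the
time-lagged intersection index relies on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "RecurrenceParams", "RecurrenceSet", "DISTANCE_REGISTRY",
    "register_distance", "log_distance_series", "select_recurrences",
    "forward_shift", "recurrence_pair",
]


# ---------------------------------------------------------------------------
# distances

def _euclidean(X: np.ndarray, x: np.ndarray) -> np.ndarray:
    diff = X - x
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def _cosine(X: np.ndarray, x: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(x)
    nX = np.linalg.norm(X, axis=1)
    if nx == 0 or np.any(nX == 0):
        raise ValueError("cosine distance undefined for zero vectors")
    return 1.0 - (X @ x) / (nX * nx)


def _standardized_euclidean(X: np.ndarray, x: np.ndarray) -> np.ndarray:
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    diff = (X - x) / scale
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


DISTANCE_REGISTRY: Dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "euclidean": _euclidean,
    "cosine": _cosine,
    "seuclidean": _standardized_euclidean,
}


def register_distance(name: str,
                      fn: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> None:
    """Register a distance ``fn(X, x) -> per-row distances`` under ``name``."""
    DISTANCE_REGISTRY[name] = fn


# ---------------------------------------------------------------------------
# parameters / result types


@dataclass(frozen=True)
class RecurrenceParams:
    """Settings that define a recurrence neighbourhood.

    q : quantile in (0, 1) of the negative-log-distance series; higher q
        means a tighter neighbourhood (typically >= 0.9).
    w : Theiler window in steps; indices with ``|t - i_ref| <= w`` are
        excluded from the candidate pool.
    metric : name of a registered distance.
    quantile_pool : "post-theiler" fixes the recurrence count from the pool
        after Theiler exclusion (default); "full" fixes it from the pool
        size before exclusion.
    """

    q: float = 0.99
    w: int = 50
    metric: str = "euclidean"
    quantile_pool: str = "post-theiler"

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must be in (0,1); got {self.q}")
        if self.w < 0:
            raise ValueError(f"Theiler window must be >= 0; got {self.w}")
        if self.metric not in DISTANCE_REGISTRY:
            raise ValueError(
                f"unknown metric {self.metric!r}; registered: "
                f"{sorted(DISTANCE_REGISTRY)}"
            )
        if self.quantile_pool not in ("post-theiler", "full"):
            raise ValueError("quantile_pool must be 'post-theiler' or 'full'")


@dataclass(frozen=True)
class RecurrenceSet:
    """Recurrences of one reference state.

    ``times`` are the selected indices (strictly increasing, all outside the
    Theiler window), ``s`` the threshold on the ``g`` scale, and ``u`` the
    positive exceedances ``g[times] - s``.
    """

    i_ref: int
    s: float
    times: np.ndarray
    u: np.ndarray
    Nn: int = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        u = np.asarray(self.u, dtype=float)
        if times.size != u.size:
            raise ValueError("times and u must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("recurrence times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "Nn", int(times.size))


# ---------------------------------------------------------------------------
# core operations


def log_distance_series(traj: Trajectory, i_ref: int,
                        metric: str = "euclidean") -> np.ndarray:
    """``g[t] = -log dist(x(t), x(i_ref))``; ``g[i_ref]`` is +inf by convention.

    An exact duplicate state at ``t != i_ref`` also yields +inf and a
    warning: it cannot carry a finite exceedance.
    """
    if metric not in DISTANCE_REGISTRY:
        raise ValueError(f"unknown metric {metric!r}")
    n = traj.n_steps
    if not 0 <= i_ref < n:
        raise IndexError(f"i_ref={i_ref} outside [0, {n})")
    d = DISTANCE_REGISTRY[metric](traj.states, traj.states[i_ref])
    with np.errstate(divide="ignore"):
        g = -np.log(d)
    g[i_ref] = np.inf
    dup = np.flatnonzero(np.isinf(g))
    if dup.size > 1:
        warnings.warn(
            f"{dup.size - 1} exact duplicate state(s) of index {i_ref} "
            "(infinite log-distance)", stacklevel=2)
    return g


def _select_from_mask(g: np.ndarray, valid: np.ndarray, q: float,
                      i_ref: int, m: Optional[int] = None) -> RecurrenceSet:
    """Rank-based selection of the ``m`` largest ``g`` over ``valid`` indices."""
    idx = np.flatnonzero(valid)
    M = idx.size
    if M < 2:
        raise ValueError(
            f"candidate pool exhausted at i_ref={i_ref} (M={M} after exclusions)")
    if m is None:
        m = max(1, math.floor((1.0 - q) * M + 1e-9))
    if m >= M:
        raise ValueError(
            f"recurrence count m={m} >= pool size M={M} at i_ref={i_ref}")
    gv = g[idx]
    neg = -gv
    kth = np.partition(neg, m)[m]
    cand = np.flatnonzero(neg <= kth)
    order = np.lexsort((idx[cand], neg[cand]))
    sel = cand[order[:m]]
    s = float(gv[cand[order[m]]])
    times = np.sort(idx[sel])
    u = g[times] - s
    if np.any(np.isinf(u)):
        warnings.warn("infinite exceedance from duplicate state(s) in the "
                      "recurrence set", stacklevel=2)
    elif np.all(u == 0):
        warnings.warn(
            f"degenerate ties at i_ref={i_ref}: all exceedances are zero",
            stacklevel=2)
    return RecurrenceSet(i_ref=i_ref, s=s, times=times, u=u)


def select_recurrences(g: np.ndarray, i_ref: int, params: RecurrenceParams,
                       pool: Optional[np.ndarray] = None,
                       m: Optional[int] = None) -> RecurrenceSet:
    """Select recurrences of ``i_ref`` from the ``g`` series.

    ``pool`` restricts the admissible indices (default: all); the Theiler
    exclusion ``|t - i_ref| <= w`` is applied here, on top of the pool.
    The count is ``m = max(1, floor((1-q) * M))`` with ``M`` the pool size
    after exclusion (or before, with ``quantile_pool="full"``); the
    threshold ``s`` is the largest non-selected ``g`` value, so every
    exceedance is positive except in the flagged all-ties case.
    """
    g = np.asarray(g, dtype=float)
    n = g.size
    valid = np.zeros(n, dtype=bool)
    if pool is None:
        valid[:] = True
    else:
        valid[np.asarray(pool, dtype=np.int64)] = True
    m_full = None
    if m is None and params.quantile_pool == "full":
        M_full = int(valid.sum())
        m_full = max(1, math.floor((1.0 - params.q) * M_full + 1e-9))
    lo = max(0, i_ref - params.w)
    hi = min(n, i_ref + params.w + 1)
    valid[lo:hi] = False
    return _select_from_mask(g, valid, params.q, i_ref,
                             m=m if m is not None else m_full)


def forward_shift(rset_or_times, L: int, n: int) -> np.ndarray:
    """Shift recurrence times by ``L`` steps (negative L = backward).

    Cardinality is preserved; any shifted index outside ``[0, n)`` is an
    error (callers restrict pools so this cannot happen in normal use).
    """
    times = rset_or_times.times if isinstance(rset_or_times, RecurrenceSet) \
        else np.asarray(rset_or_times, dtype=np.int64)
    shifted = times + int(L)
    if shifted.size and (shifted.min() < 0 or shifted.max() >= n):
        raise IndexError(
            f"forward shift by L={L} leaves the index range [0, {n})")
    return shifted


def _pair_from_g(g_ref: np.ndarray, g_fwd: np.ndarray, i_ref: int, L: int,
                 n: int, params: RecurrenceParams
                 ) -> Tuple[RecurrenceSet, RecurrenceSet]:
    """Recurrence sets at ``i_ref`` and ``i_ref + L`` over matched pools.

    The reference set draws from indices whose L-shifted image exists; the
    forward set draws from exactly those images (the same pool shifted by
    L), so every shifted membership test is defined and neither set can
    reach indices structurally invisible to the other.  The common count
    ``m`` is fixed from the smaller of the two post-Theiler pools (they can
    differ near the trajectory edges), which makes ``Nn`` identical for the
    two sets by construction.
    """
    j_ref = i_ref + L
    pool1 = np.zeros(n, dtype=bool)
    pool1[max(0, -L): n - max(0, L)] = True
    pool2 = np.zeros(n, dtype=bool)
    pool2[max(0, L): n - max(0, -L)] = True

    def theiler(pool: np.ndarray, center: int) -> np.ndarray:
        v = pool.copy()
        v[max(0, center - params.w): min(n, center + params.w + 1)] = False
        return v

    v1, v2 = theiler(pool1, i_ref), theiler(pool2, j_ref)
    if params.quantile_pool == "full":
        M = int(pool1.sum())
    else:
        M = min(int(v1.sum()), int(v2.sum()))
    if M < 2:
        raise ValueError(f"candidate pool exhausted for (i_ref={i_ref}, L={L})")
    m = max(1, math.floor((1.0 - params.q) * M + 1e-9))
    rs1 = _select_from_mask(g_ref, v1, params.q, i_ref, m=m)
    rs2 = _select_from_mask(g_fwd, v2, params.q, j_ref, m=m)
    return rs1, rs2


def recurrence_pair(traj: Trajectory, i_ref: int, L: int,
                    params: RecurrenceParams
                    ) -> Tuple[RecurrenceSet, RecurrenceSet]:
    """Recurrence sets of the reference state and of its image ``L`` steps on.

    Both sets use the same parameters; the reference set's pool is
    ``{t : 0 <= t < N and 0 <= t+L < N}`` and the forward set's pool is its
    L-shifted image, so the two sets contain the same number of recurrences
    and the intersection is unbiased by trajectory edges.  The Theiler
    exclusion is centred on each set's own reference index.
    """
    n = traj.n_steps
    if not 0 <= i_ref < n:
        raise IndexError(f"i_ref={i_ref} outside [0, {n})")
    if not 0 <= i_ref + L < n:
        raise IndexError(f"i_ref+L={i_ref + L} outside [0, {n})")
    g1 = log_distance_series(traj, i_ref, params.metric)
    g2 = g1 if L == 0 else log_distance_series(traj, i_ref + L, params.metric)
    return _pair_from_g(g1, g2, i_ref, L, n, params)
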