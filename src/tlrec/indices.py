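"""Local dynamical indices: time-lagged recurrence, dimension, persistence.

The time-lagged recurrence index ``alpha`` of a reference state at horizon
``eta = L * dt`` is the fraction of the state's recurrences whose
``L``-step-forward images are recurrences of the reference state's own
future position: ``alpha = |shift(R, L) & R_fwd| / Nn``.  It lies in
``[0, 1]``, equals 1 at ``L = 0``, and reads as a state- and
horizon-dependent predictability: neighbours of a predictable state travel
together with it.

Two companions from the same recurrence sets: the local dimension
``d = 1/sigma`` with ``sigma`` the maximum-likelihood scale of the
exponential (shape-zero generalized Pareto) distribution of exceedances,
and the persistence ``Theta = 1/theta`` with ``theta`` the Sueveges
extremal index of the recurrence times — the mean number of consecutive
steps the trajectory lingers near the state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .recurrence import (RecurrenceParams, RecurrenceSet, _pair_from_g,
                         forward_shift, log_distance_series,
                         select_recurrences)
from .trajectory import Trajectory

__all__ = [
    "AlphaField", "alpha", "alpha_conditional", "alpha_backward",
    "alpha_sweep", "local_dimension", "extremal_index",
    "compute_indices_table", "realtime_alpha_proxy", "valid_reference_indices",
]


@dataclass(frozen=True)
class AlphaField:
    """alpha values on a (reference index x horizon) grid.

    ``horizons_steps`` are integer step counts L (eta = L * dt; negative L
    allowed for backward analysis); ``eta_ell`` is an optional Lyapunov time
    for expressing the horizon axis in Lyapunov units.
    """

    refs: np.ndarray
    horizons_steps: np.ndarray
    alpha: np.ndarray
    params: RecurrenceParams
    dt: float = 1.0
    eta_ell: Optional[float] = None

    def __post_init__(self) -> None:
        refs = np.asarray(self.refs, dtype=np.int64)
        hs = np.asarray(self.horizons_steps, dtype=np.int64)
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (refs.size, hs.size):
            raise ValueError(
                f"alpha shape {a.shape} != ({refs.size}, {hs.size})")
        if a.size and (a.min() < 0 or a.max() > 1):
            raise ValueError("alpha entries must lie in [0, 1]")
        object.__setattr__(self, "refs", refs)
        object.__setattr__(self, "horizons_steps", hs)
        object.__setattr__(self, "alpha", a)

    def mean_alpha(self) -> np.ndarray:
        """Average predictability per horizon (column means)."""
        return self.alpha.mean(axis=0)

    def horizon_axis(self) -> np.ndarray:
        """Horizons in Lyapunov-time units when ``eta_ell`` is set, else steps."""
        if self.eta_ell is not None:
            return self.horizons_steps * self.dt / self.eta_ell
        return self.horizons_steps.astype(float)

    def to_frame(self) -> pd.DataFrame:
        cols = {"index": self.refs, "time": self.refs * self.dt}
        for j, L in enumerate(self.horizons_steps):
            cols[f"alpha_L{int(L)}"] = self.alpha[:, j]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, params: RecurrenceParams,
                   dt: float = 1.0, eta_ell: Optional[float] = None
                   ) -> "AlphaField":
        acols = [c for c in df.columns if c.startswith("alpha_L")]
        hs = np.array([int(c[len("alpha_L"):]) for c in acols])
        return cls(refs=df["index"].to_numpy(), horizons_steps=hs,
                   alpha=df[acols].to_numpy(), params=params, dt=dt,
                   eta_ell=eta_ell)


# ---------------------------------------------------------------------------
# alpha


def _alpha_from_sets(rs_ref: RecurrenceSet, rs_fwd: RecurrenceSet, L: int,
                     n: int) -> float:
    shifted = forward_shift(rs_ref, L, n)
    inter = np.intersect1d(shifted, rs_fwd.times, assume_unique=True)
    return inter.size / rs_ref.Nn


def alpha(traj: Trajectory, i_ref: int, L: int,
          params: RecurrenceParams) -> float:
    """Time-lagged recurrence index at ``i_ref`` for an ``L``-step horizon.

    Computed as an exact integer-index set intersection; ``L`` may be
    negative (backward analysis).  ``L = 0`` gives 1 for every state.
    """
    from .recurrence import recurrence_pair
    rs_ref, rs_fwd = recurrence_pair(traj, i_ref, L, params)
    return _alpha_from_sets(rs_ref, rs_fwd, L, traj.n_steps)


def alpha_conditional(traj: Trajectory, i_ref: int, L: int,
                      params: RecurrenceParams) -> float:
    """alpha as the empirical conditional probability of staying recurrent.

    The fraction of recurrence times ``t`` of the reference state whose
    shifted index ``t + L`` belongs to the forward-reference-state
    recurrence set.  Equals :func:`alpha` exactly — the two are the same
    count written two ways — and is kept as an independent code path.
    """
    from .recurrence import recurrence_pair
    rs_ref, rs_fwd = recurrence_pair(traj, i_ref, L, params)
    fwd_times = set(int(t) for t in rs_fwd.times)
    hits = sum(1 for t in rs_ref.times if int(t) + L in fwd_times)
    return hits / rs_ref.Nn


def alpha_backward(traj: Trajectory, i_ref: int, L_negative: int,
                   params: RecurrenceParams) -> float:
    """alpha for a non-positive horizon: how trajectories approach the state.

    Equals the forward alpha at the mirrored reference index of the
    time-reversed trajectory.
    """
    if L_negative > 0:
        raise ValueError(f"backward horizon must be <= 0; got {L_negative}")
    return alpha(traj, i_ref, L_negative, params)


def valid_reference_indices(n: int, horizons_steps: Sequence[int],
                            w: int = 0) -> np.ndarray:
    """Indices usable as references for every horizon in the list."""
    hs = np.asarray(horizons_steps, dtype=np.int64)
    lo = max(0, int(-hs.min())) if hs.size else 0
    hi = n - (max(0, int(hs.max())) if hs.size else 0)
    return np.arange(lo, hi, dtype=np.int64)


def alpha_sweep(traj: Trajectory, refs: Union[str, int, Sequence[int]],
                horizons_steps: Sequence[int], params: RecurrenceParams,
                seed: int = 0, eta_ell: Optional[float] = None) -> AlphaField:
    """alpha over a grid of reference states and horizons.

    ``refs`` is "all", an integer (seeded uniform subsample of that size,
    without replacement), or an explicit index sequence.  References are
    filtered to those valid for every horizon.  The full sweep is
    O(|refs| * |horizons| * N) in distance evaluations; subsampling
    (default benchmark: 2000 references) keeps it tractable at N = 1e5.
    """
    n = traj.n_steps
    hs = np.asarray(horizons_steps, dtype=np.int64)
    if hs.size == 0:
        raise ValueError("need at least one horizon")
    valid = valid_reference_indices(n, hs)
    if isinstance(refs, str):
        if refs != "all":
            raise ValueError(f"refs must be 'all', an int, or indices; got {refs!r}")
        chosen = valid
    elif isinstance(refs, (int, np.integer)):
        if refs <= 0:
            raise ValueError("sample size must be positive")
        rng = np.random.default_rng(seed)
        k = min(int(refs), valid.size)
        chosen = np.sort(rng.choice(valid, size=k, replace=False))
    else:
        chosen = np.asarray(refs, dtype=np.int64)
        ok = np.isin(chosen, valid)
        if not np.all(ok):
            raise IndexError(
                f"reference indices invalid for the horizon grid: "
                f"{chosen[~ok][:5].tolist()}...")
    if chosen.size == 0:
        raise ValueError("no valid reference indices for the horizon grid")

    a = np.empty((chosen.size, hs.size))
    for i, r in enumerate(chosen):
        g_ref = log_distance_series(traj, int(r), params.metric)
        for j, L in enumerate(hs):
            L = int(L)
            if L == 0:
                a[i, j] = 1.0
                continue
            g_fwd = log_distance_series(traj, int(r) + L, params.metric)
            rs1, rs2 = _pair_from_g(g_ref, g_fwd, int(r), L, n, params)
            a[i, j] = _alpha_from_sets(rs1, rs2, L, n)
    return AlphaField(refs=chosen, horizons_steps=hs, alpha=a, params=params,
                      dt=traj.dt, eta_ell=eta_ell)


# ---------------------------------------------------------------------------
# dimension and persistence


def local_dimension(rset: RecurrenceSet) -> float:
    """Local dimension ``d = 1/sigma`` from the exceedances of one state.

    ``sigma`` is the maximum-likelihood scale of an exponential fit (the
    sample mean of the exceedances); the shape parameter is fixed at zero.
    """
    if rset.Nn < 2:
        raise ValueError("need at least 2 recurrences to estimate a dimension")
    u = rset.u
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite exceedances (duplicate states); "
                         "dimension undefined")
    sigma = float(u.mean())
    if sigma <= 0:
        raise ValueError("all exceedances zero (degenerate ties); "
                         "dimension undefined")
    return 1.0 / sigma


def extremal_index(rset: RecurrenceSet, q: float) -> Tuple[float, float]:
    """Sueveges extremal index ``theta`` and persistence ``Theta = 1/theta``.

    Maximum-likelihood estimator on the inter-recurrence gaps
    ``T_i = times[i+1] - times[i]`` with ``S_i = T_i - 1`` and ``p = 1 - q``:
    with ``N_c = #{S_i > 0}`` and ``K = sum(p * S_i)``,

        theta = (K + (Nn-1) + N_c - sqrt((K + (Nn-1) + N_c)^2 - 8 N_c K)) / (2K)

    clamped to ``(0, 1]``.  ``K = 0`` (every gap is one step: a single run
    of consecutive recurrences) falls back to ``theta = 1/Nn``, the
    one-cluster limit.  ``Theta`` is the mean residence time near the state,
    in sampling steps.
    """
    if rset.Nn < 2:
        raise ValueError("insufficient recurrences for the extremal index")
    gaps = np.diff(rset.times)
    S = gaps - 1
    p = 1.0 - q
    Nc = int(np.count_nonzero(S > 0))
    K = float(p * S.sum())
    nn1 = rset.Nn - 1
    if K == 0.0 or Nc == 0:
        theta = 1.0 / rset.Nn
    else:
        b = K + nn1 + Nc
        disc = b * b - 8.0 * Nc * K
        theta = (b - math.sqrt(max(disc, 0.0))) / (2.0 * K)
        theta = min(max(theta, 1.0 / rset.Nn), 1.0)
    return theta, 1.0 / theta


def compute_indices_table(traj: Trajectory,
                          refs: Union[str, int, Sequence[int]],
                          horizons_steps: Sequence[int],
                          params: RecurrenceParams, seed: int = 0,
                          eta_ell: Optional[float] = None) -> pd.DataFrame:
    """Per-reference-state d, theta, Theta and alpha columns.

    d and theta come from the plain recurrence set of each reference (full
    pool, Theiler-excluded); the alpha columns reuse the sweep machinery.
    Output columns: ``index, time, d, theta, Theta, alpha_L<value>, ...``.
    """
    field = alpha_sweep(traj, refs, horizons_steps, params, seed=seed,
                        eta_ell=eta_ell)
    d = np.empty(field.refs.size)
    th = np.empty(field.refs.size)
    for i, r in enumerate(field.refs):
        g = log_distance_series(traj, int(r), params.metric)
        rs = select_recurrences(g, int(r), params)
        d[i] = local_dimension(rs)
        th[i], _ = extremal_index(rs, params.q)
    df = field.to_frame()
    df.insert(2, "d", d)
    df.insert(3, "theta", th)
    df.insert(4, "Theta", 1.0 / th)
    return df


# ---------------------------------------------------------------------------
# real-time proxy


def realtime_alpha_proxy(history: Trajectory, state_new, L: int,
                         params: RecurrenceParams, Na: int,
                         alpha_cache: AlphaField) -> float:
    """Analog-based predictability proxy for an unprecedented state.

    The direct index needs the state's future; in real time that is not
    available, so the proxy averages the cached alpha of the ``Na`` nearest
    past states (analogues) instead.  Analogues are restricted to the
    cached references, de-duplicated Theiler-style: among temporally
    adjacent candidates (within ``params.w`` steps of an already accepted
    analogue) only the closest is kept.
    """
    if Na < 1:
        raise ValueError(f"Na must be >= 1; got {Na}")
    try:
        col = int(np.flatnonzero(alpha_cache.horizons_steps == L)[0])
    except IndexError:
        raise ValueError(
            f"horizon L={L} not present in the alpha cache "
            f"(has {alpha_cache.horizons_steps.tolist()})") from None
    x = np.asarray(state_new, dtype=float).ravel()
    if x.size != history.n_vars:
        raise ValueError(f"state_new must be a {history.n_vars}-vector")
    from .recurrence import DISTANCE_REGISTRY
    dist = DISTANCE_REGISTRY[params.metric](history.states[alpha_cache.refs], x)
    order = np.argsort(dist, kind="stable")
    accepted: list = []
    for k in order:
        t = int(alpha_cache.refs[k])
        if all(abs(t - ta) > params.w for ta in accepted):
            accepted.append(t)
        if len(accepted) == Na:
            break
    if len(accepted) < Na:
        raise ValueError(
            f"only {len(accepted)} valid analogues for Na={Na} "
            "(history too short or Theiler window too wide)")
    ref_pos = {int(r): i for i, r in enumerate(alpha_cache.refs)}
    vals = [alpha_cache.alpha[ref_pos[t], col] for t in accepted]
    return float(np.mean(vals))
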