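"""Seeded generators for benchmark dynamical systems.

Fixed-step 4th-order Runge-Kutta integrators for the Lorenz-63, Roessler and
double-pendulum systems, an Euler-Maruyama variant of Lorenz-63 with additive
diffusion, and a Benettin-type maximum-Lyapunov-exponent estimator.  These
make the whole package testable with no external data: every simulator is
bit-reproducible given (params, init, seed, dt, n_steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "OdeSystem", "LyapunovEstimate",
    "lorenz63_system", "rossler_system", "double_pendulum_system",
    "simulate_lorenz63", "simulate_lorenz63_stochastic",
    "simulate_rossler", "simulate_double_pendulum",
    "double_pendulum_energy", "max_lyapunov_benettin", "horizon_steps",
]


@dataclass(frozen=True)
class OdeSystem:
    """An autonomous ODE ``dx/dt = rhs(x)`` with named parameters."""

    name: str
    rhs: Callable[[np.ndarray], np.ndarray]
    params: Mapping[str, float]
    dim: int
    default_init: Optional[tuple] = None


@dataclass(frozen=True)
class LyapunovEstimate:
    """Maximum Lyapunov exponent and the derived Lyapunov time.

    ``eta_ell = 1 / lambda_max`` exactly; ``se`` is the standard error of
    the per-block divergence rates.
    """

    lambda_max: float
    eta_ell: float
    n_renorm: int
    se: float


# ---------------------------------------------------------------------------
# vector fields


def lorenz63_system(sigma: float = 10.0, rho: float = 28.0,
                    beta: float = 8.0 / 3.0) -> OdeSystem:
    def rhs(v: np.ndarray) -> np.ndarray:
        x, y, z = v
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    return OdeSystem("lorenz63", rhs, dict(sigma=sigma, rho=rho, beta=beta),
                     3, default_init=(1.0, 1.0, 1.0))


def rossler_system(a: float = 0.2, b: float = 0.2, c: float = 5.7) -> OdeSystem:
    def rhs(v: np.ndarray) -> np.ndarray:
        x, y, z = v
        return np.array([-y - z, x + a * y, b + z * (x - c)])

    return OdeSystem("rossler", rhs, dict(a=a, b=b, c=c), 3,
                     default_init=(0.0, -6.78, 0.02))


def double_pendulum_system(m1: float = 1.0, m2: float = 1.0, l1: float = 1.0,
                           l2: float = 1.0, g: float = 9.81) -> OdeSystem:
    """Two-angle / two-momentum Hamiltonian form; state (th1, th2, p1, p2)."""

    def rhs(v: np.ndarray) -> np.ndarray:
        th1, th2, p1, p2 = v
        delta = th1 - th2
        cd, sd = math.cos(delta), math.sin(delta)
        denom = m1 + m2 * sd * sd
        th1dot = (l2 * p1 - l1 * p2 * cd) / (l1 * l1 * l2 * denom)
        th2dot = (l1 * (m1 + m2) * p2 - l2 * m2 * p1 * cd) / (l1 * l2 * l2 * m2 * denom)
        c1 = p1 * p2 * sd / (l1 * l2 * denom)
        c2 = (l2 * l2 * m2 * p1 * p1 + l1 * l1 * (m1 + m2) * p2 * p2
              - 2.0 * l1 * l2 * m2 * p1 * p2 * cd) \
            * math.sin(2.0 * delta) / (2.0 * l1 * l1 * l2 * l2 * denom * denom)
        p1dot = -(m1 + m2) * g * l1 * math.sin(th1) - c1 + c2
        p2dot = -m2 * g * l2 * math.sin(th2) + c1 - c2
        return np.array([th1dot, th2dot, p1dot, p2dot])

    return OdeSystem("double_pendulum", rhs,
                     dict(m1=m1, m2=m2, l1=l1, l2=l2, g=g), 4,
                     default_init=(2.0, 2.5, 0.0, 0.0))


def double_pendulum_energy(state, m1: float = 1.0, m2: float = 1.0,
                           l1: float = 1.0, l2: float = 1.0,
                           g: float = 9.81) -> np.ndarray:
    """Total energy of (th1, th2, p1, p2) states (rows or a single vector)."""
    s = np.atleast_2d(np.asarray(state, dtype=float))
    th1, th2, p1, p2 = s[:, 0], s[:, 1], s[:, 2], s[:, 3]
    cd = np.cos(th1 - th2)
    denom = m1 + m2 * np.sin(th1 - th2) ** 2
    kin = (l2 ** 2 * m2 * p1 ** 2 + l1 ** 2 * (m1 + m2) * p2 ** 2
           - 2.0 * m2 * l1 * l2 * p1 * p2 * cd) / (2.0 * l1 ** 2 * l2 ** 2 * m2 * denom)
    pot = -(m1 + m2) * g * l1 * np.cos(th1) - m2 * g * l2 * np.cos(th2)
    e = kin + pot
    return e[0] if np.ndim(state) == 1 else e


# ---------------------------------------------------------------------------
# integrators


class BlowUpError(RuntimeError):
    """Raised when an integration leaves the finite range."""


def _rk4_step(rhs, v: np.ndarray, dt: float) -> np.ndarray:
    k1 = rhs(v)
    k2 = rhs(v + 0.5 * dt * k1)
    k3 = rhs(v + 0.5 * dt * k2)
    k4 = rhs(v + dt * k3)
    return v + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _check_finite(v: np.ndarray, step: int, name: str) -> None:
    if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > 1e12:
        raise BlowUpError(f"{name}: non-finite blow-up at step {step}")


def integrate_rk4(system: OdeSystem, n_steps: int, dt: float,
                  init: Optional[Sequence[float]] = None,
                  discard: int = 0) -> Trajectory:
    """Fixed-step RK4 integration; the first ``discard`` steps are dropped."""
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1; got {n_steps}")
    if not dt > 0:
        raise ValueError(f"dt must be > 0; got {dt}")
    if discard < 0:
        raise ValueError(f"discard must be >= 0; got {discard}")
    v = np.asarray(init if init is not None else system.default_init,
                   dtype=float)
    if v.shape != (system.dim,):
        raise ValueError(f"init must be a {system.dim}-vector")
    rhs = system.rhs
    for i in range(discard):
        v = _rk4_step(rhs, v, dt)
        if i % 128 == 0:
            _check_finite(v, i, system.name)
    out = np.empty((n_steps, system.dim))
    out[0] = v
    for i in range(1, n_steps):
        v = _rk4_step(rhs, v, dt)
        out[i] = v
    _check_finite(out[-1], discard + n_steps - 1, system.name)
    if not np.all(np.isfinite(out)):
        bad = int(np.argwhere(~np.isfinite(out))[0, 0])
        raise BlowUpError(f"{system.name}: non-finite blow-up at step {discard + bad}")
    return Trajectory(out, dt=dt, meta=f"{system.name} RK4 {system.params}")


def simulate_lorenz63(n_steps: int, dt: float = 5e-3, sigma: float = 10.0,
                      rho: float = 28.0, beta: float = 8.0 / 3.0,
                      init: Optional[Sequence[float]] = None,
                      discard: int = 10_000) -> Trajectory:
    """Lorenz-63 trajectory at the classical chaotic parameters by default.

    The default protocol (dt=5e-3, a 10^4-step discarded transient) samples
    the attractor densely enough for recurrence analysis with a Theiler
    window of ~50 steps.
    """
    sys_ = lorenz63_system(sigma, rho, beta)
    traj = integrate_rk4(sys_, n_steps, dt, init=init, discard=discard)
    out = Trajectory(traj.states, dt, labels=("x", "y", "z"), meta=traj.meta)
    return out


def simulate_lorenz63_stochastic(n_steps: int, dt: float = 5e-3,
                                 sigma: float = 10.0, rho: float = 28.0,
                                 beta: float = 8.0 / 3.0,
                                 noise_amp: float = 0.5, seed: int = 0,
                                 init: Optional[Sequence[float]] = None,
                                 discard: int = 10_000) -> Trajectory:
    """Lorenz-63 with additive isotropic diffusion, Euler-Maruyama stepping.

    Each component receives ``noise_amp * sqrt(dt) * N(0,1)`` per step.
    With ``noise_amp=0`` the stepping reduces exactly to deterministic Euler.
    """
    if noise_amp < 0:
        raise ValueError(f"noise_amp must be >= 0; got {noise_amp}")
    sys_ = lorenz63_system(sigma, rho, beta)
    rng = np.random.default_rng(seed)
    v = np.asarray(init if init is not None else sys_.default_init, dtype=float)
    sqdt = math.sqrt(dt)
    for i in range(discard):
        v = v + dt * sys_.rhs(v)
        if noise_amp > 0:
            v = v + noise_amp * sqdt * rng.standard_normal(3)
        if i % 128 == 0:
            _check_finite(v, i, "lorenz63-stochastic")
    out = np.empty((n_steps, 3))
    out[0] = v
    for i in range(1, n_steps):
        v = v + dt * sys_.rhs(v)
        if noise_amp > 0:
            v = v + noise_amp * sqdt * rng.standard_normal(3)
        out[i] = v
    if not np.all(np.isfinite(out)):
        bad = int(np.argwhere(~np.isfinite(out))[0, 0])
        raise BlowUpError(f"lorenz63-stochastic: blow-up at step {discard + bad}")
    return Trajectory(out, dt, labels=("x", "y", "z"),
                      meta=f"lorenz63 Euler-Maruyama noise_amp={noise_amp} seed={seed}")


def simulate_rossler(n_steps: int, dt: float = 0.05, a: float = 0.2,
                     b: float = 0.2, c: float = 5.7,
                     init: Optional[Sequence[float]] = None,
                     discard: int = 5_000) -> Trajectory:
    traj = integrate_rk4(rossler_system(a, b, c), n_steps, dt, init=init,
                         discard=discard)
    return Trajectory(traj.states, dt, labels=("x", "y", "z"), meta=traj.meta)


def simulate_double_pendulum(n_steps: int, dt: float = 1e-3, m1: float = 1.0,
                             m2: float = 1.0, l1: float = 1.0, l2: float = 1.0,
                             g: float = 9.81,
                             init: Optional[Sequence[float]] = None,
                             discard: int = 0) -> Trajectory:
    traj = integrate_rk4(double_pendulum_system(m1, m2, l1, l2, g), n_steps,
                         dt, init=init, discard=discard)
    return Trajectory(traj.states, dt, labels=("theta1", "theta2", "p1", "p2"),
                      meta=traj.meta)


# ---------------------------------------------------------------------------
# Lyapunov


def max_lyapunov_benettin(system: OdeSystem, dt: float, n_steps: int,
                          renorm_every: int = 10, seed: int = 0,
                          init: Optional[Sequence[float]] = None,
                          d0: float = 1e-8, discard: int = 1_000,
                          warmup_frac: float = 0.1,
                          n_blocks: int = 20) -> LyapunovEstimate:
    """Maximum Lyapunov exponent by renormalised shadow perturbation.

    A reference trajectory and a shadow displaced by ``d0`` along a random
    (seeded) direction are integrated side by side with RK4; every
    ``renorm_every`` steps the separation is measured, its log accumulated,
    and the shadow is rescaled back to ``d0`` along the current separation
    direction.  The first ``warmup_frac`` of renormalisation events is
    excluded so the perturbation can align with the most unstable direction
    before averaging.  ``lambda_max`` is the mean log stretch per unit time;
    ``se`` is a standard error over ``n_blocks`` consecutive blocks.
    """
    if renorm_every < 1:
        raise ValueError(f"renorm_every must be >= 1; got {renorm_every}")
    rng = np.random.default_rng(seed)
    x = np.asarray(init if init is not None else system.default_init, dtype=float)
    rhs = system.rhs
    for i in range(discard):
        x = _rk4_step(rhs, x, dt)
        if i % 128 == 0:
            _check_finite(x, i, system.name)
    u = rng.standard_normal(system.dim)
    u /= np.linalg.norm(u)
    y = x + d0 * u

    n_renorm = n_steps // renorm_every
    if n_renorm < 2:
        raise ValueError("n_steps too small for the renormalisation interval")
    logs = np.empty(n_renorm)
    for k in range(n_renorm):
        for _ in range(renorm_every):
            x = _rk4_step(rhs, x, dt)
            y = _rk4_step(rhs, y, dt)
        _check_finite(x, (k + 1) * renorm_every, system.name)
        sep = y - x
        d = float(np.linalg.norm(sep))
        if d == 0.0:
            raise BlowUpError("shadow trajectory collapsed onto the reference")
        logs[k] = math.log(d / d0)
        y = x + sep * (d0 / d)

    warm = int(warmup_frac * n_renorm)
    used = logs[warm:]
    tau = renorm_every * dt
    lam = float(np.sum(used) / (used.size * tau))
    if lam == 0.0:
        raise ValueError("estimated lambda_max is exactly zero; Lyapunov time undefined")
    nb = min(n_blocks, used.size)
    blocks = np.array_split(used, nb)
    rates = np.array([b.mean() / tau for b in blocks])
    se = float(rates.std(ddof=1) / math.sqrt(nb)) if nb > 1 else 0.0
    return LyapunovEstimate(lambda_max=lam, eta_ell=1.0 / lam,
                            n_renorm=n_renorm, se=se)


def horizon_steps(eta_in_lyap_units: float, eta_ell: float, dt: float) -> int:
    """Convert a horizon in Lyapunov-time units to an integer step count.

    ``L = round(eta_in_lyap_units * eta_ell / dt)``; an L that rounds to 0
    means the requested horizon is below the sampling resolution and is an
    error.
    """
    if eta_in_lyap_units <= 0 or eta_ell <= 0 or dt <= 0:
        raise ValueError("all inputs to horizon_steps must be positive")
    L = int(round(eta_in_lyap_units * eta_ell / dt))
    if L == 0:
        raise ValueError(
            f"horizon {eta_in_lyap_units} Lyapunov times is below the "
            f"sampling resolution dt={dt}"
        )
    return L
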