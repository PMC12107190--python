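import numpy as np
import pytest

from tlrec import RecurrenceParams, Trajectory, simulate_lorenz63


@pytest.fixture(scope="session")
def lorenz_small():
    """Short on-attractor Lorenz-63 trajectory for cheap unit tests."""
    return simulate_lorenz63(5_000, discard=2_000)


@pytest.fixture(scope="session")
def small_params():
    return RecurrenceParams(q=0.95, w=10)


@pytest.fixture()
def random_traj():
    """Factory for seeded random-walk trajectories."""
    def make(seed: int, n: int = 300, d: int = 2) -> Trajectory:
        rng = np.random.default_rng(seed)
        steps = rng.standard_normal((n, d))
        return Trajectory(np.cumsum(steps, axis=0), dt=1.0)
    return make


def brute_force_select(g, i_ref, q, w, pool=None):
    """Independent oracle: full sort by (-g, index) over the admissible pool."""
    g = np.asarray(g, dtype=float)
    n = g.size
    cand = np.arange(n) if pool is None else np.asarray(pool)
    cand = cand[np.abs(cand - i_ref) > w]
    order = sorted(cand, key=lambda t: (-g[t], t))
    m = max(1, int(np.floor((1 - q) * len(order))))
    times = sorted(order[:m])
    s = g[order[m]]
    return np.array(times), float(s)


def brute_force_alpha(X, i_ref, L, q, w):
    """Independent oracle for the time-lagged recurrence index."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    pool1 = np.arange(max(0, -L), n - max(0, L))
    pool2 = pool1 + L

    def rec(pool, center):
        cand = pool[np.abs(pool - center) > w]
        d = np.linalg.norm(X[cand] - X[center], axis=1)
        order = sorted(range(cand.size), key=lambda i: (d[i], cand[i]))
        return cand, order

    c1, o1 = rec(pool1, i_ref)
    c2, o2 = rec(pool2, i_ref + L)
    m = max(1, int(np.floor((1 - q) * min(c1.size, c2.size))))
    r1 = set(int(c1[i]) for i in o1[:m])
    r2 = set(int(c2[i]) for i in o2[:m])
    return len({t + L for t in r1} & r2) / m
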