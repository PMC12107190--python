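import numpy as np
import pytest

from tlrec import (AlphaField, RecurrenceParams, RecurrenceSet, Trajectory,
                   alpha, alpha_backward, alpha_conditional, alpha_sweep,
                   compute_indices_table, extremal_index, local_dimension,
                   realtime_alpha_proxy, valid_reference_indices)

from conftest import brute_force_alpha


class TestAlpha:
    def test_zero_horizon_is_one(self, lorenz_small, small_params):
        for i_ref in (0, 777, 4999):
            assert alpha(lorenz_small, i_ref, 0, small_params) == 1.0

    def test_bounds(self, lorenz_small, small_params):
        for i_ref, L in [(50, 200), (2500, -400), (4000, 999)]:
            a = alpha(lorenz_small, i_ref, L, small_params)
            assert 0.0 <= a <= 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, random_traj, seed):
        traj = random_traj(seed, n=250, d=2)
        p = RecurrenceParams(q=0.9, w=5)
        for i_ref, L in [(80, 30), (120, -40)]:
            assert alpha(traj, i_ref, L, p) == \
                brute_force_alpha(traj.states, i_ref, L, 0.9, 5)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_periodic_orbit_fully_predictable(self):
        # sinusoid in 2-D: neighbourhoods travel rigidly around the cycle, so
        # alpha = 1 at every horizon commensurate with the sampled period
        th = 2 * np.pi / 100.0 * (np.arange(500) % 100)
        traj = Trajectory(np.column_stack([np.sin(th), np.cos(th)]), dt=1.0)
        p = RecurrenceParams(q=0.9, w=5)
        for i_ref in (20, 120):
            for L in (100, 200, 300):
                assert alpha(traj, i_ref, L, p) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_conditional_form_identical(self, random_traj, seed):
        traj = random_traj(seed, n=300, d=2)
        p = RecurrenceParams(q=0.92, w=6)
        for i_ref, L in [(100, 25), (200, -60), (40, 0)]:
            assert alpha(traj, i_ref, L, p) == \
                alpha_conditional(traj, i_ref, L, p)

    @pytest.mark.parametrize("seed", range(4))
    def test_time_reversal_duality(self, random_traj, seed):
        traj = random_traj(seed, n=280, d=2)
        p = RecurrenceParams(q=0.9, w=4)
        n = traj.n_steps
        for i_ref, k in [(150, 30), (200, 75)]:
            back = alpha_backward(traj, i_ref, -k, p)
            fwd = alpha(traj.reversed(), n - 1 - i_ref, k, p)
            assert back == fwd

    def test_backward_rejects_positive(self, lorenz_small, small_params):
        with pytest.raises(ValueError, match="<= 0"):
            alpha_backward(lorenz_small, 100, 5, small_params)


class TestAlphaSweep:
    def test_diffusion_noise_lowers_mean_alpha(self):
        # additive noise blurs neighbourhood evolution: average predictability
        # at a fixed horizon must not exceed the deterministic run's
        from tlrec import simulate_lorenz63_stochastic
        p = RecurrenceParams(q=0.97, w=20)
        det = simulate_lorenz63_stochastic(20_000, noise_amp=0.0, seed=0,
                                           discard=5_000)
        noisy = simulate_lorenz63_stochastic(20_000, noise_amp=1.0, seed=0,
                                             discard=5_000)
        m_det = alpha_sweep(det, 150, [44], p, seed=1).alpha.mean()
        m_noisy = alpha_sweep(noisy, 150, [44], p, seed=1).alpha.mean()
        assert m_noisy <= m_det + 0.02


    def test_zero_horizon_field(self, lorenz_small, small_params):
        f = alpha_sweep(lorenz_small, 40, [0], small_params, seed=0)
        assert np.all(f.alpha == 1.0)

    def test_seeded_subsample_deterministic(self, lorenz_small, small_params):
        a = alpha_sweep(lorenz_small, 30, [11, 44], small_params, seed=5)
        b = alpha_sweep(lorenz_small, 30, [11, 44], small_params, seed=5)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.refs, b.refs)

    def test_ref_validity_filtering(self, lorenz_small):
        v = valid_reference_indices(lorenz_small.n_steps, [-10, 100])
        assert v[0] == 10 and v[-1] == lorenz_small.n_steps - 101
        with pytest.raises(IndexError, match="invalid"):
            alpha_sweep(lorenz_small, [2, 4999], [100],
                        RecurrenceParams(q=0.95, w=10))

    def test_horizon_axis_units(self, lorenz_small, small_params):
        f = alpha_sweep(lorenz_small, 10, [11, 220], small_params, seed=1,
                        eta_ell=1.1)
        np.testing.assert_allclose(f.horizon_axis(),
                                   np.array([11, 220]) * 0.005 / 1.1)

    def test_frame_round_trip(self, lorenz_small, small_params):
        f = alpha_sweep(lorenz_small, 15, [11, 44], small_params, seed=2)
        back = AlphaField.from_frame(f.to_frame(), small_params,
                                     dt=lorenz_small.dt)
        np.testing.assert_array_equal(back.alpha, f.alpha)
        np.testing.assert_array_equal(back.horizons_steps, f.horizons_steps)


def _rset(times, u):
    times = np.asarray(times)
    u = np.asarray(u, dtype=float)
    return RecurrenceSet(i_ref=0, s=1.0, times=times, u=u)


class TestLocalDimension:
    def test_closed_form(self):
        assert local_dimension(_rset([1, 2, 3], [0.5, 0.5, 0.5])) == 2.0

    def test_exponential_recovery(self):
        rng = np.random.default_rng(11)
        u = rng.exponential(scale=1.0 / 3.0, size=10_000)
        d = local_dimension(_rset(np.arange(u.size), u))
        assert d == pytest.approx(3.0, abs=0.1)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            local_dimension(_rset([1], [0.3]))
        with pytest.raises(ValueError, match="undefined"):
            local_dimension(_rset([1, 2], [0.0, 0.0]))


class TestExtremalIndex:
    def test_isolated_recurrences_closed_form(self):
        # evenly spread recurrence times: no clustering, theta = 1
        th, Th = extremal_index(_rset([10, 20, 30, 40], [1, 1, 1, 1]), q=0.99)
        assert th == pytest.approx(1.0, abs=1e-3)
        assert Th == pytest.approx(1.0, abs=1e-3)

    def test_single_run_fallback(self):
        th, Th = extremal_index(_rset([10, 11, 12, 13], [1, 1, 1, 1]), q=0.99)
        assert th == 0.25 and Th == 4.0

    def test_insufficient(self):
        with pytest.raises(ValueError, match="nsufficient"):
            extremal_index(_rset([5], [1.0]), q=0.99)

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_run_length_recovery(self, k):
        # runs of k consecutive recurrences at seeded Poisson-spaced starts
        rng = np.random.default_rng(k)
        q = 0.99
        starts = np.cumsum(rng.geometric(p=(1 - q) / k, size=400)) + \
            k * np.arange(400)
        times = (starts[:, None] + np.arange(k)).ravel()
        th, Th = extremal_index(_rset(times, np.ones(times.size)), q=q)
        assert th == pytest.approx(1.0 / k, abs=0.15 / k)
        assert Th == pytest.approx(1.0 / th)


class TestIndicesTable:
    def test_columns_and_identity(self, lorenz_small, small_params):
        df = compute_indices_table(lorenz_small, 25, [11, 44], small_params,
                                   seed=4)
        assert list(df.columns) == ["index", "time", "d", "theta", "Theta",
                                    "alpha_L11", "alpha_L44"]
        np.testing.assert_allclose(df["Theta"] * df["theta"], 1.0)
        assert (df["d"] > 0).all()
        assert df["theta"].between(0, 1).all()

    def test_explicit_refs_row_count(self, lorenz_small, small_params):
        df = compute_indices_table(lorenz_small, [100, 200], [11],
                                   small_params)
        assert len(df) == 2
        assert df["index"].tolist() == [100, 200]


class TestRealtimeProxy:
    def _cache(self, lorenz_small, small_params, n=60):
        return alpha_sweep(lorenz_small, n, [44], small_params, seed=9)

    def test_identity_analogue(self, lorenz_small, small_params):
        cache = self._cache(lorenz_small, small_params)
        r = int(cache.refs[10])
        val = realtime_alpha_proxy(lorenz_small, lorenz_small.states[r], 44,
                                   small_params, 1, cache)
        assert val == cache.alpha[10, 0]

    def test_mean_of_analogues(self, lorenz_small, small_params):
        cache = AlphaField(refs=np.array([100, 400, 800]),
                           horizons_steps=np.array([44]),
                           alpha=np.array([[0.2], [0.4], [0.6]]),
                           params=small_params, dt=lorenz_small.dt)
        val = realtime_alpha_proxy(lorenz_small, np.zeros(3), 44,
                                   small_params, 3, cache)
        assert val == pytest.approx(0.4)

    def test_errors(self, lorenz_small, small_params):
        cache = self._cache(lorenz_small, small_params, n=5)
        with pytest.raises(ValueError, match="analogues"):
            realtime_alpha_proxy(lorenz_small, lorenz_small.states[0], 44,
                                 small_params, 50, cache)
        with pytest.raises(ValueError, match="horizon"):
            realtime_alpha_proxy(lorenz_small, lorenz_small.states[0], 11,
                                 small_params, 1, cache)
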