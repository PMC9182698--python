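import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spelearn.learners import (
    KalmanParams,
    KalmanState,
    RWParams,
    RWState,
    SPEParams,
    SPEState,
    high_noise_gain,
    kalman_update,
    run_kalman,
    run_rw,
    run_spe,
    rw_update,
    spe_delta,
    spe_update,
    steady_state_gain,
    steady_state_posterior_var,
)

finite_rewards = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


def iterate_kalman_variance(nu, sigma, w0=1.0, n=10_000, tol=0.0):
    """Independent oracle: iterate the variance/gain recursion directly."""
    w = w0
    k = None
    for _ in range(n):
        prior = w + nu**2
        k = prior / (prior + sigma**2)
        w_new = (1.0 - k) * prior
        if tol and abs(w_new - w) < tol:
            return w_new, k
        w = w_new
    return w, k


class TestSPEDelta:
    def test_unit_spread_identity(self):
        assert spe_delta(SPEState(m=0.0, s=1.0), 1.0) == 1.0

    def test_zero_error_at_mean(self):
        assert spe_delta(SPEState(m=3.7, s=2.2), 3.7) == 0.0

    def test_scaling(self):
        assert spe_delta(SPEState(m=0.0, s=2.0), 4.0) == 2.0

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_nonfinite_reward_rejected(self, bad):
        with pytest.raises(ValueError):
            spe_delta(SPEState(m=0.0, s=1.0), bad)

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ValueError):
            SPEState(m=0.0, s=0.0)


class TestSPEUpdate:
    def test_hand_arithmetic(self):
        # delta = (4-0)/2 = 2; m' = 0 + 0.1*2; s' = 2 + 0.05*(4-1)
        params = SPEParams(alpha_m=0.1, alpha_s=0.05)
        new, delta = spe_update(SPEState(m=0.0, s=2.0), params, 4.0)
        assert delta == 2.0
        assert new.m == pytest.approx(0.2, abs=1e-15)
        assert new.s == pytest.approx(2.15, abs=1e-15)

    def test_delta_from_pre_update_state(self):
        params = SPEParams(alpha_m=1.0, alpha_s=0.0)
        state = SPEState(m=1.0, s=2.0)
        _, delta = spe_update(state, params, 5.0)
        assert delta == (5.0 - 1.0) / 2.0

    def test_spread_floor_applies(self):
        params = SPEParams(alpha_m=0.1, alpha_s=10.0, s_floor=0.5)
        new, _ = spe_update(SPEState(m=0.0, s=1.0), params, 0.0)
        # raw update: 1 + 10*(0 - 1) = -9 -> floored
        assert new.s == 0.5

    @given(rewards=st.lists(finite_rewards, min_size=1, max_size=50))
    def test_rw_reduction_bit_identical(self, rewards):
        spe_params = SPEParams(alpha_m=0.3, alpha_s=0.0, m0=0.0, s0=1.0)
        rw_params = RWParams(alpha=0.3, m0=0.0)
        spe_state = spe_params.initial_state()
        rw_state = rw_params.initial_state()
        for r in rewards:
            spe_state, d_spe = spe_update(spe_state, spe_params, r)
            rw_state, d_rw = rw_update(rw_state, rw_params, r)
            assert spe_state.m == rw_state.m
            assert d_spe == d_rw
            assert spe_state.s == 1.0

    def test_stochastic_fixed_point(self, rng):
        # at (m, s) = (mu, sigma) the expected one-step updates vanish
        mu, sigma = 2.0, 3.0
        n = 1_000_000
        params = SPEParams(alpha_m=0.1, alpha_s=0.1)
        r = rng.normal(mu, sigma, n)
        delta = (r - mu) / sigma
        dm = params.alpha_m * delta
        ds = params.alpha_s * (delta**2 - 1.0)
        for updates in (dm, ds):
            sem = updates.std(ddof=1) / math.sqrt(n)
            assert abs(updates.mean()) < 4 * sem

    def test_stochastic_fixed_point_non_gaussian(self, rng):
        # holds for any distribution with matching first two moments
        r = rng.uniform(-1.0, 1.0, 500_000)  # mean 0, sd 1/sqrt(3)
        mu, sigma = 0.0, 1.0 / math.sqrt(3.0)
        delta = (r - mu) / sigma
        for updates in (delta, delta**2 - 1.0):
            sem = updates.std(ddof=1) / math.sqrt(updates.size)
            assert abs(updates.mean()) < 4 * sem


class TestRWUpdate:
    def test_full_update_limit(self):
        new, _ = rw_update(RWState(m=0.0), RWParams(alpha=1.0), 5.0)
        assert new.m == 5.0

    def test_half_update(self):
        new, delta = rw_update(RWState(m=0.0), RWParams(alpha=0.5), 4.0)
        assert delta == 4.0
        assert new.m == 2.0

    @given(r=finite_rewards)
    def test_frozen_learner(self, r):
        new, _ = rw_update(RWState(m=1.5), RWParams(alpha=0.0), r)
        assert new.m == 1.5

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            RWParams(alpha=1.5)


class TestKalmanUpdate:
    def test_noiseless_observation(self):
        params = KalmanParams(nu=1.0, sigma=0.0)
        new, _ = kalman_update(KalmanState(m=-3.0, w=2.0), params, 7.0)
        assert new.k == 1.0
        assert new.m == 7.0

    def test_one_step_values(self):
        params = KalmanParams(nu=1.0, sigma=1.0)
        new, _ = kalman_update(KalmanState(m=0.0, w=1.0), params, 1.0)
        assert new.k == pytest.approx(2.0 / 3.0, abs=1e-15)
        assert new.w == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_gain_converges_to_steady_state(self):
        params = KalmanParams(nu=1.0, sigma=3.0, w0=5.0)
        state = params.initial_state()
        for _ in range(200):
            state, _ = kalman_update(state, params, 0.0)
        assert state.k == pytest.approx(steady_state_gain(1.0, 3.0), abs=1e-10)

    def test_degenerate_gain_error(self):
        with pytest.raises(ValueError):
            KalmanParams(nu=0.0, sigma=0.0)

    @given(
        nu=st.floats(min_value=0.01, max_value=100.0),
        sigma=st.floats(min_value=0.0, max_value=100.0),
        w0=st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=50)
    def test_gain_and_variance_bounds(self, nu, sigma, w0):
        params = KalmanParams(nu=nu, sigma=sigma, w0=w0)
        state = params.initial_state()
        for _ in range(20):
            state, _ = kalman_update(state, params, 1.0)
            assert 0.0 <= state.k <= 1.0
            assert state.w >= 0.0


class TestSteadyState:
    def test_noiseless_limit(self):
        assert steady_state_gain(1.0, 0.0) == 1.0

    def test_gain_against_iteration_oracle(self):
        k_exact = steady_state_gain(1.0, 2.0)
        _, k_iter = iterate_kalman_variance(1.0, 2.0, n=1000)
        assert k_exact == pytest.approx(k_iter, abs=1e-12)
        assert k_exact == pytest.approx(0.390, abs=5e-4)

    def test_high_noise_gain_limit(self):
        # k_inf / (nu/sigma) -> 1 as sigma/nu -> infinity
        ratios = [
            steady_state_gain(1.0, s) / high_noise_gain(1.0, s)
            for s in (10.0, 100.0, 1000.0, 10000.0)
        ]
        assert all(np.diff(np.abs(np.array(ratios) - 1.0)) < 0)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)

    def test_posterior_var_golden_ratio(self):
        w_exact = steady_state_posterior_var(1.0, 1.0)
        assert w_exact == pytest.approx((math.sqrt(5.0) - 1.0) / 2.0, abs=1e-15)
        w_iter, _ = iterate_kalman_variance(1.0, 1.0, n=1000)
        assert w_exact == pytest.approx(w_iter, abs=1e-12)

    def test_posterior_var_zero_process_noise(self):
        assert steady_state_posterior_var(0.0, 1.0) == 0.0
        assert steady_state_gain(0.0, 1.0) == 0.0

    def test_posterior_var_high_noise_geometric_mean(self):
        nu, sigma = 1.0, 1000.0
        assert steady_state_posterior_var(nu, sigma) == pytest.approx(
            nu * sigma, rel=1e-3
        )

    @pytest.mark.parametrize("nu", np.logspace(-2, 2, 5))
    @pytest.mark.parametrize("sigma", np.logspace(-2, 2, 5))
    @pytest.mark.parametrize("w0", [0.0, 1.0, 50.0])
    def test_iteration_converges_from_any_w0(self, nu, sigma, w0):
        w_iter, k_iter = iterate_kalman_variance(nu, sigma, w0=w0, n=100_000)
        assert w_iter == pytest.approx(
            steady_state_posterior_var(nu, sigma), abs=1e-8, rel=1e-8
        )
        assert k_iter == pytest.approx(steady_state_gain(nu, sigma), abs=1e-8)

    @given(
        nu=st.floats(min_value=1e-3, max_value=1e3),
        sigma=st.floats(min_value=0.0, max_value=1e3),
    )
    def test_gain_in_unit_interval(self, nu, sigma):
        assert 0.0 < steady_state_gain(nu, sigma) <= 1.0


class TestHighNoiseGain:
    def test_unit_ratio(self):
        assert high_noise_gain(1.0, 1.0) == 1.0

    def test_direct_ratio(self):
        assert high_noise_gain(1.0, 5.0) == 0.2

    def test_within_30_percent_at_sigma_2(self):
        k = steady_state_gain(1.0, 2.0)
        assert abs(k - high_noise_gain(1.0, 2.0)) / k < 0.30

    def test_approximation_improves_with_noise(self):
        def rel_err(sigma):
            k = steady_state_gain(1.0, sigma)
            return abs(k - high_noise_gain(1.0, sigma)) / k

        assert rel_err(10.0) < rel_err(2.0)

    def test_sigma_zero_rejected(self):
        with pytest.raises(ValueError):
            high_noise_gain(1.0, 0.0)


class TestRunners:
    def test_run_rw_matches_stepwise(self, rng):
        rewards = rng.normal(size=200)
        params = RWParams(alpha=0.37, m0=0.5)
        trace = run_rw(params, rewards)
        state = params.initial_state()
        for t, r in enumerate(rewards):
            state, delta = rw_update(state, params, r)
            assert trace.m[t] == pytest.approx(state.m, abs=1e-12)
            assert trace.delta[t] == pytest.approx(delta, abs=1e-12)

    def test_run_spe_matches_stepwise(self, rng):
        rewards = rng.normal(size=200)
        params = SPEParams(alpha_m=0.2, alpha_s=0.05)
        trace = run_spe(params, rewards)
        state = params.initial_state()
        for t, r in enumerate(rewards):
            state, delta = spe_update(state, params, r)
            assert trace.m[t] == state.m
            assert trace.s[t] == state.s
            assert trace.delta[t] == delta

    def test_run_kalman_matches_stepwise(self, rng):
        rewards = rng.normal(size=100)
        params = KalmanParams(nu=0.5, sigma=2.0, w0=1.0)
        trace = run_kalman(params, rewards)
        state = params.initial_state()
        for t, r in enumerate(rewards):
            state, _ = kalman_update(state, params, r)
            assert trace.m[t] == state.m
            assert trace.w[t] == state.w
            assert trace.k[t] == state.k
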