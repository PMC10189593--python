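"""Markov-chain core: transition structure, stationary law, win probability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropgame import (
    ModelParams,
    build_transition_matrix,
    critical_theta,
    soil_stationary,
    stationary_distribution,
    win_probability_randomized,
    win_region,
)


def geometric_stationary(K: int, gamma: float) -> np.ndarray:
    """Closed form for a=b=1: detailed balance gives x_i proportional to r^i."""
    r = gamma / (1.0 - gamma)
    if np.isclose(r, 1.0):
        return np.full(K + 1, 1.0 / (K + 1))
    x = r ** np.arange(K + 1)
    return x / x.sum()


class TestTransitionMatrix:
    def test_symmetric_three_state_walk(self):
        T = build_transition_matrix(ModelParams(K=2, theta=0), gamma=0.5)
        expected = np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
        np.testing.assert_allclose(T, expected)

    def test_pure_cover_jumps_up(self):
        p = ModelParams(K=5, theta=0, a=2, b=1)
        T = build_transition_matrix(p, gamma=1.0)
        for i in range(6):
            assert T[i, min(i + 2, 5)] == 1.0

    def test_boundary_clipping_accumulates(self):
        p = ModelParams(K=10, theta=0, a=1, b=3)
        T = build_transition_matrix(p, gamma=0.3)
        assert T[2, 3] == pytest.approx(0.3)
        assert T[2, 0] == pytest.approx(0.7)  # 2 - 3 clips to 0

    @given(
        K=st.integers(2, 20),
        a=st.integers(1, 5),
        b=st.integers(1, 5),
        gamma=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rows_are_stochastic(self, K, a, b, gamma):
        p = ModelParams(K=K, theta=0, a=min(a, K), b=min(b, K))
        T = build_transition_matrix(p, gamma)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(T >= 0) and np.all(T <= 1)
        assert np.all((T > 0).sum(axis=1) <= 3)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(ModelParams(K=2, theta=0), gamma=1.5)


class TestStationaryDistribution:
    def test_symmetric_walk_is_uniform(self):
        T = build_transition_matrix(ModelParams(K=2, theta=0), gamma=0.5)
        np.testing.assert_allclose(stationary_distribution(T), np.full(3, 1 / 3),
                                   atol=1e-12)

    @pytest.mark.parametrize("gamma", [0.1, 0.3, 0.5, 0.6, 0.7, 0.9])
    def test_matches_geometric_closed_form(self, gamma):
        p = ModelParams(K=10, theta=0)
        x = soil_stationary(p, gamma)
        assert np.abs(x - geometric_stationary(10, gamma)).max() < 1e-10

    @pytest.mark.parametrize("gamma,pinned", [(0.0, 0), (1.0, 10)])
    def test_endpoints_are_point_masses(self, gamma, pinned):
        x = soil_stationary(ModelParams(K=10, theta=0), gamma)
        assert x[pinned] == 1.0 and x.sum() == 1.0

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.2], [0.3, 0.7]]))


class TestWinProbability:
    def test_worked_example_both_timings(self, base_params):
        # frozen from independent closed-form geometric sums
        assert win_probability_randomized(base_params, 0.6, "post") == pytest.approx(
            0.5448, abs=2e-4
        )
        assert win_probability_randomized(base_params, 0.6, "pre") == pytest.approx(
            0.5511, abs=2e-4
        )

    @pytest.mark.parametrize("timing", ["pre", "post"])
    def test_monoculture_limits_exact(self, base_params, timing):
        assert win_probability_randomized(base_params, 0.0, timing) == base_params.p1
        assert win_probability_randomized(base_params, 1.0, timing) == base_params.p

    @pytest.mark.parametrize("timing", ["pre", "post"])
    def test_parrondo_effect_exists(self, base_params, timing):
        """Two losing monocultures combine into a winning mixture."""
        assert win_probability_randomized(base_params, 0.0, timing) < 0.5
        assert win_probability_randomized(base_params, 1.0, timing) < 0.5
        assert win_probability_randomized(base_params, 0.6, timing) > 0.5

    def test_continuous_in_gamma(self, base_params):
        grid = np.linspace(0.01, 0.99, 99)
        vals = [win_probability_randomized(base_params, g) for g in grid]
        jumps = np.abs(np.diff(vals))
        # numerical Lipschitz estimate from a 10x finer grid
        fine = np.linspace(0.01, 0.99, 981)
        fvals = [win_probability_randomized(base_params, g) for g in fine]
        lip = np.abs(np.diff(fvals)).max() / (fine[1] - fine[0])
        assert jumps.max() <= 1.5 * lip * (grid[1] - grid[0])


class TestWinRegion:
    def test_contains_example_gamma(self, base_params):
        r = win_region(base_params)
        assert r.exists
        assert r.gamma_min < 0.6 < r.gamma_max
        mid = 0.5 * (r.gamma_min + r.gamma_max)
        assert win_probability_randomized(base_params, mid) > 0.5

    def test_no_region_when_all_probs_below_half(self, losing_params):
        assert not win_region(losing_params).exists

    @pytest.mark.parametrize("theta", [2, 5, 10])
    def test_matches_dense_grid_oracle(self, base_params, theta):
        p = base_params.with_theta(theta)
        r = win_region(p)
        dense = np.arange(1e-4, 1.0, 1e-3)
        wins = np.array([win_probability_randomized(p, g) > 0.5 for g in dense])
        assert r.exists == wins.any()
        if r.exists:
            assert abs(r.gamma_min - dense[wins].min()) < 2e-3
            assert abs(r.gamma_max - dense[wins].max()) < 2e-3

    def test_boundaries_bracket_half(self, base_params):
        r = win_region(base_params, refine_tol=1e-8)
        for g in (r.gamma_min, r.gamma_max):
            below = win_probability_randomized(base_params, g - 1e-6)
            above = win_probability_randomized(base_params, g + 1e-6)
            assert min(below, above) < 0.5 < max(below, above)


class TestCriticalTheta:
    def test_none_when_unwinnable(self, losing_params):
        assert critical_theta(losing_params) is None

    def test_at_least_theta_two_for_worked_example(self, base_params):
        ts = critical_theta(base_params)
        assert ts is not None and ts >= 2

    def test_winnability_is_monotone_in_theta(self, base_params):
        """Full scan: no winnable theta above an unwinnable one."""
        winnable = [
            win_region(base_params.with_theta(t)).exists
            for t in range(base_params.K + 1)
        ]
        ts = critical_theta(base_params)
        assert winnable == [t <= ts for t in range(base_params.K + 1)]

    def test_theta_star_non_increasing_in_depletion_ratio(self):
        """Faster soil depletion (b/a up) never raises the critical threshold."""
        stars = []
        for b in (1, 2, 3):
            p = ModelParams(K=10, theta=0, a=1, b=b)
            ts = critical_theta(p)
            stars.append(-1 if ts is None else ts)
        assert stars == sorted(stars, reverse=True)
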