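"""Unit tests for the two-strategy game: payoffs, dynamics, equilibria."""

import math

import numpy as np
import pytest

from sungame import (
    PayoffParameters,
    build_payoff_matrix,
    closed_form_trajectory,
    constant_difference,
    expected_payoffs,
    find_equilibria,
    integrate_replicator,
    phase_portrait,
    replicator_rate,
)

# Full-precision Australia-average game primitives (rounded: B=585, C=10790, E=2339)
AVG = PayoffParameters(benefit=585.0, cost=10790.0, externality=2339.0)


class TestPayoffMatrix:
    def test_zero_parameters_give_zero_matrix(self):
        m = build_payoff_matrix(PayoffParameters(0, 0, 0))
        assert m.cc == m.cd == m.dc == (0.0, 0.0) or m.dd == (0.0, 0.0)
        assert m.cc == (0.0, 0.0) and m.cd == (0.0, 0.0)
        assert m.dc == (0.0, 0.0) and m.dd == (0.0, 0.0)

    @pytest.mark.parametrize(
        "params",
        [AVG, PayoffParameters(100, 20, 7), PayoffParameters(0, 5, 123.5, subsidy=2)],
    )
    def test_mutual_defection_costs_each_player_the_externality(self, params):
        m = build_payoff_matrix(params)
        assert m.dd == (-params.externality, -params.externality)

    def test_australia_average_entries(self):
        m = build_payoff_matrix(AVG)
        assert m.cc == (-10205.0, -10205.0)
        assert m.cd == (-12544.0, 0.0)

    def test_symmetric_game_transpose(self):
        m = build_payoff_matrix(AVG)
        assert m.cd == (m.dc[1], m.dc[0])

    def test_subsidy_enters_as_effective_cost(self):
        with_s = build_payoff_matrix(PayoffParameters(585, 10790, 2339, subsidy=500))
        without = build_payoff_matrix(PayoffParameters(585, 10290, 2339))
        assert with_s == without

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="cost"):
            PayoffParameters(1, -1, 0)
        with pytest.raises(ValueError, match="benefit"):
            PayoffParameters(math.nan, 0, 0)


class TestExpectedPayoffs:
    def test_full_cooperation_removes_the_externality(self):
        pay = expected_payoffs(AVG, 1.0)
        assert pay.pi_defector == 0.0
        assert pay.pi_cooperator == AVG.benefit - AVG.cost

    def test_full_defection_australia_average(self):
        pay = expected_payoffs(AVG, 0.0)
        assert pay.pi_cooperator == -12544.0
        assert pay.pi_defector == -2339.0

    @pytest.mark.parametrize("x", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_payoff_gap_is_constant_in_population_share(self, x):
        pay = expected_payoffs(AVG, x)
        assert pay.pi_cooperator - pay.pi_defector == pytest.approx(
            AVG.benefit - AVG.cost, abs=1e-9
        )

    @pytest.mark.parametrize("x", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_average_payoff_is_share_weighted(self, x):
        pay = expected_payoffs(AVG, x)
        assert pay.pi_average == pytest.approx(
            x * pay.pi_cooperator + (1 - x) * pay.pi_defector, abs=1e-12
        )

    def test_state_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            expected_payoffs(AVG, 1.5)


class TestReplicatorRate:
    def test_boundaries_are_fixed_points(self):
        g = constant_difference(123.4)
        assert replicator_rate(g, 0.0) == 0.0
        assert replicator_rate(g, 1.0) == 0.0

    def test_australia_average_rate_at_half(self):
        g = constant_difference(-10205.23)
        assert replicator_rate(g, 0.5) == pytest.approx(-2551.31, abs=0.005)

    @pytest.mark.parametrize("k", [-5.0, -0.1, 0.1, 5.0])
    @pytest.mark.parametrize("x", [0.01, 0.3, 0.7, 0.99])
    def test_interior_rate_sign_matches_payoff_gap(self, k, x):
        assert math.copysign(1, replicator_rate(constant_difference(k), x)) == math.copysign(1, k)


class TestClosedFormTrajectory:
    times = np.linspace(0.0, 10.0, 101)

    @pytest.mark.parametrize("x0", [0.0, 1.0])
    def test_absorbing_boundaries(self, x0):
        traj = closed_form_trajectory(AVG, x0, self.times)
        assert np.all(traj.states == x0)

    def test_positive_gap_converges_to_full_adoption(self):
        params = PayoffParameters(585, 10790, 2339, subsidy=10790)  # k = +585
        traj = closed_form_trajectory(params, 0.01, np.linspace(0, 10, 11))
        assert traj.states[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(traj.states) >= 0)
        assert traj.states[1] > traj.states[0]

    def test_unit_negative_gap_value(self):
        params = PayoffParameters(0, 1, 0)  # k = -1
        traj = closed_form_trajectory(params, 0.5, np.array([0.0, 1.0]))
        assert traj.states[-1] == pytest.approx(0.26894142137, abs=1e-9)

    def test_huge_coefficient_saturates_without_overflow(self):
        params = PayoffParameters(1e4, 0, 0)
        traj = closed_form_trajectory(params, 0.5, np.linspace(0, 10, 5))
        assert np.all(np.isfinite(traj.states))
        assert traj.states[-1] == 1.0


class TestNumericalIntegrator:
    times = np.linspace(0.0, 10.0, 101)

    @pytest.mark.parametrize("k", [-1e4, -100.0, -1.0, 0.5, 250.0, 1e4])
    def test_matches_logistic_closed_form(self, k):
        b, c = (k, 0.0) if k > 0 else (0.0, -k)
        params = PayoffParameters(b, c, 0)
        exact = closed_form_trajectory(params, 0.3, self.times)
        num = integrate_replicator(constant_difference(k), 0.3, self.times)
        assert np.max(np.abs(num.states - exact.states)) <= 1e-6

    def test_neutral_dynamics_stay_put(self):
        traj = integrate_replicator(constant_difference(0.0), 0.42, self.times)
        assert np.all(traj.states == 0.42)

    def test_frequency_dependent_gap_moves_past_tipping_point(self):
        traj = integrate_replicator(lambda x: x - 0.5, 0.6, np.linspace(0, 200, 51))
        assert np.all(np.diff(traj.states) >= 0)
        assert traj.states[-1] > 0.99

    def test_nonmonotone_time_grid_rejected(self):
        with pytest.raises(ValueError):
            integrate_replicator(constant_difference(1.0), 0.5, [0.0, 2.0, 1.0])


class TestEquilibria:
    def test_positive_gap_adoption_regime(self):
        rep = find_equilibria(constant_difference(3.0))
        assert rep.regime == "adoption"
        assert rep.stability_of(0.0) == "unstable"
        assert rep.stability_of(1.0) == "stable"
        assert len(rep.equilibria) == 2

    def test_negative_gap_free_riding_regime(self):
        rep = find_equilibria(constant_difference(-10205.23))
        assert rep.regime == "free_riding"
        assert rep.stability_of(0.0) == "stable"
        assert rep.stability_of(1.0) == "unstable"

    def test_neutral_gap_reports_continuum(self):
        rep = find_equilibria(constant_difference(0.0))
        assert rep.regime == "neutral"
        assert rep.continuum

    def test_interior_tipping_point_matches_grid_scan_oracle(self):
        g = lambda x: x - 0.5
        rep = find_equilibria(g)
        interior = [eq for eq in rep.equilibria if 0 < eq.x < 1]
        assert len(interior) == 1
        assert interior[0].x == pytest.approx(0.5, abs=1e-9)
        assert interior[0].stability == "unstable"
        assert rep.stability_of(0.0) == "stable"
        assert rep.stability_of(1.0) == "stable"
        assert rep.regime == "frequency_dependent"

        # brute-force oracle: sign pattern of xdot on a fine grid
        xs = np.linspace(1e-4, 1 - 1e-4, 4001)
        rates = xs * (1 - xs) * (xs - 0.5)
        flips = np.flatnonzero(np.diff(np.sign(rates)) != 0)
        assert len(flips) == 1
        x_star = 0.5 * (xs[flips[0]] + xs[flips[0] + 1])
        assert x_star == pytest.approx(interior[0].x, abs=1e-3)
        # flow points away on both sides -> unstable
        assert rates[flips[0]] < 0 < rates[flips[0] + 1]


class TestPhasePortrait:
    def test_five_point_constant_gap(self):
        pp = phase_portrait(constant_difference(4.0), n_grid=5)
        assert np.allclose(pp[:, 0], [0, 0.25, 0.5, 0.75, 1.0])
        assert np.allclose(pp[:, 1], [0, 0.75, 1.0, 0.75, 0])

    def test_endpoints_always_rest(self):
        pp = phase_portrait(lambda x: math.sin(7 * x) - 0.2, n_grid=33)
        assert pp[0, 1] == 0.0 and pp[-1, 1] == 0.0

    def test_interior_rates_negative_in_free_riding_regime(self):
        pp = phase_portrait(AVG.payoff_difference(), n_grid=41)
        assert np.all(pp[1:-1, 1] < 0)

    def test_rate_maximal_at_half_for_constant_gap(self):
        pp = phase_portrait(constant_difference(2.0), n_grid=101)
        assert np.argmax(np.abs(pp[:, 1])) == 50

    def test_too_few_grid_points_rejected(self):
        with pytest.raises(ValueError):
            phase_portrait(constant_difference(1.0), n_grid=2)
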