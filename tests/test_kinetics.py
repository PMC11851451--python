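"""Sensorgram simulators (closed form and ODE) and global 1:1 fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from groovebind import (
    InjectionSchedule,
    OneSiteKinetics,
    OneSiteKineticsModel,
    Sensorgram,
    TwoSiteKinetics,
    equilibrium_constant_from_rates,
    fraction_bound_one_site,
    fraction_bound_two_site,
    simulate_one_site_sensorgram,
    simulate_two_site_sensorgram,
)
from groovebind.kinetics import simulate_single_cycle
from groovebind.synthetic import generate_sensorgram_set


@pytest.fixture
def schedule():
    return InjectionSchedule(t_start=0.0, t_stop=600.0, t_end=1200.0, C_inject=5e-8)


class TestOneSiteSimulator:
    def test_against_independent_ode_integration(self, db2009_kinetics, schedule):
        """Closed form must track dR/dt = ka*C*(Rmax-R) - kd*R to < 1e-6 RU."""
        p = OneSiteKinetics(ka=db2009_kinetics.ka, kd=db2009_kinetics.kd, Rmax=100.0)
        grid = np.linspace(0.0, 1200.0, 400)
        sg = simulate_one_site_sensorgram(p, schedule, grid)

        def rhs(t, y):
            C = schedule.C_inject if t <= schedule.t_stop else 0.0
            return p.ka * C * (p.Rmax - y[0]) - p.kd * y[0]

        ref = np.empty_like(grid)
        y = [0.0]
        masks = [grid <= schedule.t_stop, grid > schedule.t_stop]
        for (t0, t1), mask in zip([(0.0, 600.0), (600.0, 1200.0)], masks):
            t_eval = np.unique(np.concatenate([grid[mask], [t1]]))
            sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, rtol=1e-12, atol=1e-12)
            idx = np.searchsorted(sol.t, grid[mask])
            ref[mask] = sol.y[0][idx]
            y = [sol.y[0][-1]]
        assert np.max(np.abs(sg.response - ref)) < 1e-6

    def test_zero_concentration_gives_zero_response(self, db2009_kinetics):
        sched = InjectionSchedule(0.0, 600.0, 1200.0, 0.0)
        sg = simulate_one_site_sensorgram(db2009_kinetics, sched)
        assert np.all(sg.response == 0.0)

    def test_long_association_plateau_is_the_equilibrium_response(self, db2009_kinetics):
        C = 5e-8
        sched = InjectionSchedule(0.0, 5000.0, 5100.0, C)
        sg = simulate_one_site_sensorgram(db2009_kinetics, sched, np.linspace(0, 5000, 100))
        K = db2009_kinetics.ka / db2009_kinetics.kd
        expected = db2009_kinetics.Rmax * fraction_bound_one_site(K, C)
        assert sg.response[-1] == pytest.approx(expected, rel=1e-6)

    def test_phase_monotonicity_and_bound(self, db2009_kinetics, schedule):
        sg = simulate_one_site_sensorgram(db2009_kinetics, schedule, np.linspace(0, 1200, 500))
        assoc = sg.association_mask()
        assert np.all(np.diff(sg.response[assoc]) >= 0)
        assert np.all(np.diff(sg.response[sg.dissociation_mask()]) <= 0)
        assert np.all(sg.response <= db2009_kinetics.Rmax + 1e-12)

    def test_empty_grid_rejected(self, db2009_kinetics, schedule):
        with pytest.raises(ValueError):
            simulate_one_site_sensorgram(db2009_kinetics, schedule, np.array([]))

    def test_single_cycle_carries_response_between_injections(self, db2009_kinetics):
        scheds = [
            InjectionSchedule(0.0, 300.0, 360.0, 1e-8),
            InjectionSchedule(360.0, 660.0, 720.0, 5e-8),
        ]
        cycles = simulate_single_cycle(db2009_kinetics, scheds)
        # second cycle starts where the first ended, not at zero
        assert cycles[1].response[0] == pytest.approx(cycles[0].response[-1], rel=1e-9)
        assert cycles[1].response[0] > 0


class TestTwoSiteSimulator:
    @pytest.fixture
    def params(self):
        # K_A1 = 2.6e6, K_A2 = 7.5e7 with relaxation fast enough to equilibrate
        return TwoSiteKinetics(ka1=2.6e4, ka2=7.5e5, kd1=1e-2, kd2=1e-2, Rmax1=50.0)

    def test_vanishing_second_step_reduces_to_one_site(self, schedule):
        p2 = TwoSiteKinetics(ka1=3.4e6, ka2=1e-8, kd1=1.19e-2, kd2=1.0, Rmax1=80.0)
        p1 = OneSiteKinetics(ka=3.4e6, kd=1.19e-2, Rmax=80.0)
        grid = np.linspace(0, 1200, 300)
        r2 = simulate_two_site_sensorgram(p2, schedule, grid).response
        r1 = simulate_one_site_sensorgram(p1, schedule, grid).response
        assert np.max(np.abs(r2 - r1)) < 1e-6

    def test_long_association_plateau_matches_equilibrium_model(self, params):
        C = 1e-7
        sched = InjectionSchedule(0.0, 20000.0, 20100.0, C)
        grid = np.linspace(0.0, 20000.0, 200)
        sg = simulate_two_site_sensorgram(params, sched, grid)
        expected = params.Rmax1 * fraction_bound_two_site(params.K_A1, params.K_A2, C)
        assert sg.response[-1] == pytest.approx(expected, rel=1e-7)

    def test_response_bounded_by_dimer_saturation(self, params):
        sched = InjectionSchedule(0.0, 20000.0, 21000.0, 1e-5)
        sg = simulate_two_site_sensorgram(params, sched, np.linspace(0, 21000, 300))
        assert np.all(sg.response <= 2.0 * params.Rmax1 + 1e-9)
        assoc = sg.association_mask()
        assert np.all(np.diff(sg.response[assoc]) >= -1e-9)
        assert np.all(np.diff(sg.response[~assoc]) <= 1e-9)


class TestEquilibriumFromRates:
    @pytest.mark.parametrize(
        "ka, kd, expected",
        [
            (3.4e6, 1.19e-2, 2.857142857142857e8),  # DB2009 at -AATT-
            (1.3e6, 5.9e-3, 2.2033898305084745e8),  # DB1898 at -AATT-
            (0.7, 0.7, 1.0),
        ],
    )
    def test_quotient(self, ka, kd, expected):
        assert equilibrium_constant_from_rates(ka, kd) == pytest.approx(expected, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            equilibrium_constant_from_rates(0.0, 1.0)
        with pytest.raises(ValueError):
            equilibrium_constant_from_rates(1.0, -1.0)


class TestGlobalKineticFit:
    def test_noiseless_recovery_is_exact_to_a_tenth_percent(self, db2009_kinetics):
        curves, _ = generate_sensorgram_set(db2009_kinetics, noise_sigma=0.0, seed=0)
        res = OneSiteKineticsModel(curves).fit()
        assert res.converged
        for name in ("ka", "kd", "Rmax"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(db2009_kinetics, name), rel=1e-3
            )
        assert res.K_A == pytest.approx(db2009_kinetics.ka / db2009_kinetics.kd, rel=2e-3)

    def test_noisy_recovery_within_ten_percent(self, db2009_kinetics):
        curves, _ = generate_sensorgram_set(db2009_kinetics, noise_sigma=2.0, seed=7)
        res = OneSiteKineticsModel(curves).fit()
        assert res.converged
        for name in ("ka", "kd", "Rmax"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(db2009_kinetics, name), rel=0.10
            )
        assert res.bse["kd"] > 0

    def test_dissociation_only_data_flags_ka_unidentifiable(self, db2009_kinetics):
        sched = InjectionSchedule(0.0, 10.0, 1210.0, 5e-8)
        t = np.linspace(10.5, 1210.0, 300)  # strictly after t_stop
        R0 = 60.0
        response = R0 * np.exp(-db2009_kinetics.kd * (t - 10.0))
        sg = Sensorgram(t, response, sched)
        res = OneSiteKineticsModel([sg]).fit()
        assert "ka" in res.unidentifiable
        assert np.isnan(res.K_A)
        assert res.params.kd == pytest.approx(db2009_kinetics.kd, rel=1e-6)

    def test_single_full_curve_rejected(self, db2009_kinetics):
        curves, _ = generate_sensorgram_set(
            db2009_kinetics, concentrations=[5e-8], noise_sigma=0.0, seed=0
        )
        with pytest.raises(ValueError, match="2 concentrations"):
            OneSiteKineticsModel(curves)

    def test_summary_mentions_all_parameters(self, db2009_kinetics):
        curves, _ = generate_sensorgram_set(
            db2009_kinetics, concentrations=[1e-8, 1e-7], noise_sigma=0.0, seed=0
        )
        text = OneSiteKineticsModel(curves).fit().summary()
        for token in ("ka", "kd", "Rmax", "K_A"):
            assert token in text
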