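"""Structural model: exact solutions, exposure metrics, and conservation laws."""

import numpy as np
import pytest

from meropk import datasets, pk_core
from meropk.exceptions import InputError, InvalidParameterError, UndefinedRatioError
from meropk.pk_core import (
    ConcentrationProfile,
    InfusionSchedule,
    StructuralParams,
    auc_trapezoid,
    daily_average_auc,
    infusion_rate,
    penetration_ratio,
    solve_profile,
    solve_profile_numeric,
    steady_state,
)

from conftest import random_params


class TestInfusionRate:
    @pytest.mark.parametrize(
        "events, t, expected",
        [
            ([(0.0, 0.25, 2000.0)], 0.1, 8000.0),
            ([(0.0, 0.25, 2000.0)], 0.3, 0.0),
            ([(0.0, 0.25, 2000.0), (0.25, 8.0, 1000.0)], 4.0, 125.0),
        ],
    )
    def test_piecewise_rate(self, events, t, expected):
        sched = InfusionSchedule(events, horizon=72.0)
        assert infusion_rate(sched, t) == pytest.approx(expected)

    def test_overlapping_events_add(self):
        sched = InfusionSchedule([(0.0, 4.0, 400.0), (2.0, 4.0, 400.0)], horizon=8.0)
        assert infusion_rate(sched, 3.0) == pytest.approx(200.0)
        assert infusion_rate(sched, 1.0) == pytest.approx(100.0)

    def test_negative_time_rejected(self):
        sched = InfusionSchedule([(0.0, 1.0, 100.0)], horizon=8.0)
        with pytest.raises(InputError):
            infusion_rate(sched, -0.5)


class TestScheduleValidation:
    def test_zero_duration_rejected(self):
        with pytest.raises(InputError):
            InfusionSchedule([(0.0, 0.0, 100.0)], horizon=8.0)

    def test_unsorted_events_rejected(self):
        with pytest.raises(InputError):
            InfusionSchedule([(8.0, 1.0, 100.0), (0.0, 1.0, 100.0)], horizon=24.0)

    def test_total_dose_prorates_the_running_infusion(self):
        sched = datasets.ci_regimen(1000.0, ld_mg=2000.0, horizon=72.0)
        # last 8-h maintenance bag starts at 64.25 h and is still running at 72 h
        expected = 2000.0 + 8 * 1000.0 + 1000.0 * (72.0 - 64.25) / 8.0
        assert sched.total_dose() == pytest.approx(expected)


class TestSolveProfile:
    def test_empty_schedule_gives_zero_profile(self, median_params):
        sched = InfusionSchedule([], horizon=24.0)
        prof = solve_profile(median_params, sched, np.linspace(0, 24, 25))
        assert np.all(prof.c_plasma == 0)
        assert np.all(prof.c_elf == 0)

    def test_invalid_parameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            StructuralParams(CL=-1, V=10, K12=1, K21=1, K13=1, K31=1, V_ELF=10)

    def test_unsorted_grid_rejected(self, median_params, ci_1g):
        with pytest.raises(InputError):
            solve_profile(median_params, ci_1g, np.array([0.0, 2.0, 1.0]))

    def test_plasma_steady_state_equals_rate_over_clearance(self, median_params):
        # continuous 1 g/8 h forever: Css = 125/CL = 11.14 mg/L
        sched = datasets.ci_regimen(1000.0, ld_mg=2000.0, horizon=400.0)
        prof = solve_profile(median_params, sched, np.linspace(0, 400, 801))
        assert prof.c_plasma[-1] == pytest.approx(125.0 / 11.219, rel=1e-6)
        assert prof.c_plasma[-1] == pytest.approx(11.14, abs=5e-3)

    def test_elf_steady_state_matches_transfer_balance(self, median_params):
        sched = datasets.ci_regimen(2000.0, ld_mg=2000.0, horizon=400.0)
        prof = solve_profile(median_params, sched, np.linspace(0, 400, 801))
        expected = (250.0 / 11.219) * (10.143 * 18.539) / (25.614 * 19.424)
        assert prof.c_elf[-1] == pytest.approx(expected, rel=1e-6)
        assert prof.c_elf[-1] == pytest.approx(8.42, abs=5e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_eigen_solution_matches_numeric_integration(self, seed, ci_2g):
        params = random_params(np.random.default_rng(seed))
        grid = pk_core.default_grid(72.0, step=0.5)
        exact = solve_profile(params, ci_2g, grid)
        numeric = solve_profile_numeric(params, ci_2g, grid)
        scale = max(exact.c_plasma.max(), 1.0)
        assert np.allclose(exact.c_plasma, numeric.c_plasma, rtol=1e-6, atol=1e-6 * scale)
        assert np.allclose(exact.c_elf, numeric.c_elf, rtol=1e-6, atol=1e-6 * scale)

    def test_mass_balance_without_elimination(self, ci_2g):
        # with negligible clearance the compartments must hold the infused dose
        params = StructuralParams(
            CL=1e-9, V=10.0, K12=5.0, K21=3.0, K13=8.0, K31=12.0, V_ELF=20.0
        )
        grid = np.linspace(0.0, 72.0, 73)
        amounts = pk_core.solve_amounts(params.as_array()[None, :], ci_2g, grid)[0]
        total = amounts.sum(axis=1)
        dosed = np.array([ci_2g.total_dose(t) for t in grid])
        assert np.allclose(total[1:], dosed[1:], rtol=1e-6)

    def test_superposition_of_loading_and_maintenance(self, median_params):
        grid = pk_core.default_grid(72.0, step=0.5)
        both = datasets.ci_regimen(1000.0, ld_mg=2000.0, horizon=72.0)
        ld_only = InfusionSchedule(both.events[:1], horizon=72.0)
        ci_only = InfusionSchedule(both.events[1:], horizon=72.0)
        p_ld = solve_profile(median_params, ld_only, grid)
        p_ci = solve_profile(median_params, ci_only, grid)
        p_both = solve_profile(median_params, both, grid)
        assert np.allclose(p_both.c_plasma, p_ld.c_plasma + p_ci.c_plasma, rtol=1e-8, atol=1e-10)
        assert np.allclose(p_both.c_elf, p_ld.c_elf + p_ci.c_elf, rtol=1e-8, atol=1e-10)

    def test_profile_converges_to_steady_state(self, mean_params):
        sched = datasets.ci_regimen(2000.0, ld_mg=2000.0, horizon=300.0)
        prof = solve_profile(mean_params, sched, np.array([0.0, 300.0]))
        css_p, css_e = steady_state(mean_params, 250.0)
        assert prof.c_plasma[-1] == pytest.approx(css_p, rel=1e-8)
        assert prof.c_elf[-1] == pytest.approx(css_e, rel=1e-8)


class TestSteadyState:
    def test_zero_rate(self, median_params):
        assert steady_state(median_params, 0.0) == (0.0, 0.0)

    def test_reference_medians(self, median_params):
        css_p, css_e = steady_state(median_params, 250.0)
        assert css_p == pytest.approx(22.28, abs=5e-3)
        assert css_e == pytest.approx(8.42, abs=5e-3)

    def test_vanishing_lung_transfer_empties_elf(self):
        params = StructuralParams(CL=10, V=10, K12=1, K21=1, K13=1e-12, K31=1, V_ELF=10)
        _, css_e = steady_state(params, 250.0)
        assert css_e == pytest.approx(0.0, abs=1e-9)

    def test_negative_rate_rejected(self, median_params):
        with pytest.raises(InputError):
            steady_state(median_params, -1.0)


class TestExposureMetrics:
    def test_auc_constant_and_linear(self):
        t = np.linspace(0, 24, 241)
        assert auc_trapezoid(np.full_like(t, 10.0), t) == pytest.approx(240.0)
        t2 = np.linspace(0, 10, 11)
        assert auc_trapezoid(t2, t2) == pytest.approx(50.0)

    def test_auc_length_mismatch(self):
        with pytest.raises(InputError):
            auc_trapezoid(np.ones(3), np.array([0.0, 1.0]))

    def test_auc_matches_closed_form_dose_over_clearance(self, median_params):
        # single dose, integrated to near-complete elimination: AUC = D/CL
        sched = InfusionSchedule([(0.0, 0.25, 2000.0)], horizon=400.0)
        grid = pk_core.default_grid(400.0, step=0.05)
        prof = solve_profile(median_params, sched, grid)
        auc = auc_trapezoid(prof.c_plasma, grid)
        assert auc == pytest.approx(2000.0 / median_params.CL, rel=1e-3)

    @pytest.mark.parametrize(
        "cum, total, expected", [(720.0, 72.0, 240.0), (240.0, 24.0, 240.0), (100.0, 48.0, 50.0)]
    )
    def test_daily_average_auc(self, cum, total, expected):
        assert daily_average_auc(cum, total) == pytest.approx(expected)

    def test_daily_average_rejects_nonpositive_time(self):
        with pytest.raises(InputError):
            daily_average_auc(100.0, 0.0)

    @pytest.mark.parametrize(
        "auc_elf, auc_plasma, expected",
        [(100.0, 100.0, 100.0), (84.1, 287.6, 29.24), (50.0, 200.0, 25.0)],
    )
    def test_penetration_ratio(self, auc_elf, auc_plasma, expected):
        assert penetration_ratio(auc_elf, auc_plasma) == pytest.approx(expected, abs=5e-3)

    def test_penetration_zero_plasma_rejected(self):
        with pytest.raises(UndefinedRatioError):
            penetration_ratio(10.0, 0.0)

    def test_steady_state_penetration_closed_form(self, median_params):
        assert pk_core.steady_state_penetration(median_params) == pytest.approx(37.8, abs=0.05)

    def test_profile_penetration_matches_closed_form_post_steady_state(self, median_params):
        sched = datasets.ci_regimen(2000.0, ld_mg=2000.0, horizon=72.0)
        grid = pk_core.default_grid(72.0)
        prof = solve_profile(median_params, sched, grid)
        mask = grid >= 48.0
        ratio = penetration_ratio(
            auc_trapezoid(prof.c_elf[mask], grid[mask]),
            auc_trapezoid(prof.c_plasma[mask], grid[mask]),
        )
        assert ratio == pytest.approx(pk_core.steady_state_penetration(median_params), rel=5e-3)


class TestConcentrationProfile:
    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ConcentrationProfile(np.array([0.0, 1.0]), np.zeros(3), np.zeros(2))

    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            ConcentrationProfile(np.array([0.0, 1.0]), np.array([0.0, -1.0]), np.zeros(2))


def test_terminal_half_life_orders_realistic_vs_degenerate(median_params):
    realistic = pk_core.terminal_half_life(median_params.as_array())[0]
    degenerate = np.array([0.01, 40.0, 30.0, 0.01, 18.0, 25.0, 20.0])
    assert realistic < 6.0
    assert pk_core.terminal_half_life(degenerate)[0] > 100.0
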