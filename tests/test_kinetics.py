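import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdxkit.cluster_io import Species, UptakeCurve
from hdxkit.kinetics import (FitError, KineticFit, Phase,
                             compute_x_plat, eval_stretched_exp,
                             fit_interpolation, fit_stretched_exponential,
                             integrate_area, select_best_nexp)


def _curve(times, uptakes, replicates=None, n_max=8):
    sp = Species("p", 1, 10, "KLSAMGTRAV", max_uptake=n_max)
    times = np.asarray(times, float)
    if replicates is None:
        replicates = np.ones(len(times), int)
    return UptakeCurve(sp, "apo", times, np.asarray(uptakes, float), replicates)


class TestEval:
    def test_zero_at_time_zero(self):
        phases = [Phase(3.0, 0.5, 0.7), Phase(2.0, 0.01, 1.0)]
        assert eval_stretched_exp(phases, 0.0) == 0.0

    def test_simple_exponential_half_life(self):
        # beta=1 reduces to 1-exp(-kt); at t = ln2/k half the amplitude
        val = eval_stretched_exp([Phase(5.0, 0.1, 1.0)], math.log(2) / 0.1)
        assert val == pytest.approx(2.5, rel=1e-12)

    def test_stretch_exponent_at_kt_one(self):
        # (kt)=1 makes the stretch exponent moot: 4*(1-e^-1)
        val = eval_stretched_exp([Phase(4.0, 0.5, 0.7)], 2.0)
        assert val == pytest.approx(4 * (1 - math.exp(-1)), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(FitError):
            eval_stretched_exp([Phase(1.0, 1.0, 1.0)], -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.floats(0.1, 20), k=st.floats(1e-4, 1e3),
           beta=st.floats(0.05, 1.0),
           t1=st.floats(1e-6, 1e5), factor=st.floats(1.0, 100.0))
    def test_monotone_nondecreasing(self, n, k, beta, t1, factor):
        phases = [Phase(n, k, beta)]
        assert eval_stretched_exp(phases, t1 * factor) >= \
            eval_stretched_exp(phases, t1) - 1e-12


class TestFit:
    def test_exact_recovery_on_noise_free_data(self):
        t = np.logspace(-1, 3, 7)
        y = 6.0 * -np.expm1(-((0.2 * t) ** 0.8))
        fit = fit_stretched_exponential(_curve(t, y), 1, 8.0)
        ph = fit.phases[0]
        assert ph.n == pytest.approx(6.0, rel=1e-3)
        assert ph.k == pytest.approx(0.2, rel=1e-3)
        assert ph.beta == pytest.approx(0.8, abs=1e-3)

    def test_two_phase_truth_prefers_two_phases(self):
        t = np.logspace(-2, 4, 12)
        y = (3.0 * -np.expm1(-(5.0 * t)) + 3.0 * -np.expm1(-(0.005 * t)))
        f1 = fit_stretched_exponential(_curve(t, y), 1, 8.0)
        f2 = fit_stretched_exponential(_curve(t, y), 2, 8.0)
        assert f2.adj_r2 > f1.adj_r2

    def test_constant_zero_uptake_degenerates_to_zero_amplitude(self):
        t = np.logspace(-1, 2, 6)
        fit = fit_stretched_exponential(_curve(t, np.zeros(6)), 1, 8.0)
        assert fit.n_total == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_points_named_error(self):
        with pytest.raises(FitError, match=r"p\[1-10\]"):
            fit_stretched_exponential(_curve([1.0, 2.0], [0.1, 0.2]), 1, 8.0,
                                      fix_n=False)

    def test_fix_n_pins_amplitude(self):
        t = np.logspace(-1, 3, 7)
        y = 6.0 * -np.expm1(-0.2 * t)
        fit = fit_stretched_exponential(_curve(t, y), 1, 6.0, fix_n=True)
        assert fit.n_total == 6.0

    def test_amplitude_bounded_by_n_max(self):
        t = np.logspace(-1, 3, 7)
        y = 6.0 * -np.expm1(-0.2 * t)
        fit = fit_stretched_exponential(_curve(t, y), 1, 4.0)
        assert fit.n_total <= 4.0 + 1e-9


class TestSelectNexp:
    def test_single_phase_truth_selects_one_phase(self):
        t = np.logspace(-1, 3, 9)
        y = 5.0 * -np.expm1(-((0.1 * t) ** 0.9))
        fit = select_best_nexp(_curve(t, y), 2, 8.0)
        assert fit.nexp == 1

    def test_max_nexp_one_equivalent_to_direct_fit(self):
        t = np.logspace(-1, 3, 7)
        y = 5.0 * -np.expm1(-0.1 * t)
        a = select_best_nexp(_curve(t, y), 1, 8.0)
        b = fit_stretched_exponential(_curve(t, y), 1, 8.0)
        assert a.phases == b.phases

    def test_well_separated_phases_select_two(self):
        t = np.logspace(-3, 4, 14)
        y = 3.0 * -np.expm1(-(10.0 * t)) + 4.0 * -np.expm1(-(0.01 * t))
        fit = select_best_nexp(_curve(t, y), 2, 8.0)
        assert fit.nexp == 2


class TestInterpolation:
    def test_passes_through_knot_means(self):
        t = np.array([1.0, 1.0, 10.0, 10.0, 100.0, 100.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 6.0])
        fit = fit_interpolation(_curve(t, y, replicates=[1, 2, 1, 2, 1, 2]))
        assert fit.evaluate(1.0) == pytest.approx(1.5)
        assert fit.evaluate(10.0) == pytest.approx(4.0)
        assert fit.evaluate(100.0) == pytest.approx(6.0)

    def test_monotone_data_gives_monotone_interpolant(self):
        t = np.array([1.0, 10.0, 100.0, 1000.0])
        y = np.array([0.5, 2.0, 3.0, 3.2])
        fit = fit_interpolation(_curve(t, y))
        grid = np.linspace(1, 1000, 500)
        vals = fit.evaluate(grid)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_rate_unavailable_for_interpolation(self):
        t = np.array([1.0, 10.0, 100.0])
        fit = fit_interpolation(_curve(t, [1.0, 2.0, 3.0]))
        with pytest.raises(FitError, match="interpolation"):
            fit.k_obs

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_interpolation(_curve([1.0], [1.0]))


def _fit(phases, t_max=1e4):
    return KineticFit(None, "apo", len(phases), tuple(phases), 1.0,
                      t_max_observed=t_max)


class TestXPlat:
    def test_closed_form_simple_exponential(self):
        fit = _fit([Phase(5.0, 0.1, 1.0)])
        assert compute_x_plat(fit, 0.99) == pytest.approx(
            math.log(100) / 0.1, rel=1e-9)

    def test_unreached_plateau_returns_none(self):
        fit = _fit([Phase(5.0, 1e-6, 1.0)], t_max=10.0)
        assert compute_x_plat(fit, 0.99) is None

    def test_multiphase_matches_grid_scan(self):
        fit = _fit([Phase(3.0, 0.5, 0.8), Phase(2.0, 0.005, 1.0)])
        x = compute_x_plat(fit, 0.99)
        grid = np.linspace(1e-6, 1e4, 2_000_001)
        target = 0.99 * 5.0
        scan = grid[np.argmax(eval_stretched_exp(fit.phases, grid) >= target)]
        assert x == pytest.approx(scan, rel=1e-5)


class TestArea:
    def test_zero_uptake_gives_zero_area(self):
        fit = _fit([Phase(0.0, 1.0, 1.0)])
        assert integrate_area(fit, (0.0, 100.0)).hdx_area == pytest.approx(0.0)

    @pytest.mark.parametrize("window", [(0.0, 50.0), (0.1, 1500.0), (2.0, 80.0)])
    def test_closed_form_simple_exponential(self, window):
        n, k = 6.0, 0.2
        fit = _fit([Phase(n, k, 1.0)])
        a, b = window
        closed = n * ((b - a) + (math.exp(-k * b) - math.exp(-k * a)) / k)
        area = integrate_area(fit, window).hdx_area
        assert area == pytest.approx(closed, rel=1e-6)

    def test_x_plat_truncates_window(self):
        fit = _fit([Phase(6.0, 0.2, 0.8)])
        full = integrate_area(fit, (0.1, 1000.0))
        trunc = integrate_area(fit, (0.1, 1000.0), x_plat=50.0)
        direct = integrate_area(fit, (0.1, 50.0))
        assert trunc.effective_upper_limit == 50.0
        assert trunc.hdx_area == pytest.approx(direct.hdx_area, rel=1e-9)
        assert trunc.hdx_area < full.hdx_area

    def test_invalid_window_rejected(self):
        fit = _fit([Phase(6.0, 0.2, 0.8)])
        with pytest.raises(FitError):
            integrate_area(fit, (10.0, 1.0))

    def test_log_time_option(self):
        fit = _fit([Phase(6.0, 0.2, 1.0)])
        res = integrate_area(fit, (0.1, 1000.0), log_time=True)
        # oracle: dense trapezoid on the log10 axis
        u = np.linspace(math.log10(0.1), math.log10(1000.0), 200001)
        ref = np.trapezoid(eval_stretched_exp(fit.phases, 10.0 ** u), u)
        assert res.hdx_area == pytest.approx(ref, rel=1e-6)


def test_adjusted_r2_never_prefers_extra_phases_on_perfect_fit():
    t = np.logspace(-1, 3, 10)
    y = 5.0 * -np.expm1(-0.1 * t)   # exactly single-phase
    fit = select_best_nexp(_curve(t, y), 3, 8.0)
    assert fit.nexp == 1
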