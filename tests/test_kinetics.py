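"""Delta time courses and two-term exponential reflex kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clickmocr.kinetics import (
    DeltaError,
    DeltaSeries,
    GridExpFitter,
    baseline_trend,
    compute_delta,
    delta_max,
    fit_two_term_exp,
    two_term_exp,
)
from clickmocr.paradigm import ParameterError

ACT_TIMES = (np.arange(62) * 2 + 0.5) / 62.5  # default sub-averaged grid (s)


def _series(values, times=ACT_TIMES, window="activation"):
    return DeltaSeries(1000.0, window, np.asarray(times, float),
                       np.asarray(values, float), "first_point")


class TestComputeDelta:
    def test_constant_magnitude_gives_zero(self):
        d = compute_delta(np.full(10, 2e-3), ACT_TIMES[:10], 1000.0, "activation")
        assert np.allclose(d.delta_db, 0.0)

    def test_halved_magnitude_is_minus_six_db(self):
        m = np.full(8, 1e-3)
        m[4:] = 0.5e-3
        d = compute_delta(m, ACT_TIMES[:8], 1000.0, "activation")
        assert d.delta_db[5] == pytest.approx(-6.0206, abs=1e-3)

    def test_reference_point_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        m = 1e-3 * (1 + 0.1 * rng.random(12))
        act = compute_delta(m, ACT_TIMES[:12], 1000.0, "activation")
        rec = compute_delta(m, ACT_TIMES[:12], 1000.0, "recovery")
        assert act.delta_db[0] == 0.0
        assert rec.delta_db[-1] == 0.0
        assert rec.reference == "last_point"

    def test_missing_points_propagate(self):
        m = np.full(10, 1e-3)
        m[3] = np.nan
        d = compute_delta(m, ACT_TIMES[:10], 1000.0, "activation")
        assert np.isnan(d.delta_db[3]) and np.isfinite(d.delta_db[4])

    def test_bad_reference_raises(self):
        m = np.full(10, 1e-3)
        m[0] = np.nan
        with pytest.raises(DeltaError):
            compute_delta(m, ACT_TIMES[:10], 1000.0, "activation")
        with pytest.raises(DeltaError):
            compute_delta(np.full(10, -1e-3), ACT_TIMES[:10], 1000.0, "activation")


TRUE_PARAMS = dict(C=-2.0, m_f=1.0, m_s=1.0, tau_f=0.2, tau_s=20.0)


class TestTwoTermFit:
    def test_model_closed_form(self):
        assert two_term_exp(0.0, **TRUE_PARAMS) == pytest.approx(0.0)
        assert two_term_exp(2.0, **TRUE_PARAMS) == pytest.approx(-1.09512, abs=1e-4)

    def test_noiseless_parameter_recovery(self):
        y = two_term_exp(ACT_TIMES, **TRUE_PARAMS)
        fit = fit_two_term_exp(_series(y))
        assert fit.converged
        for name, truth in TRUE_PARAMS.items():
            got = getattr(fit, name if name != "C" else "C")
            assert got == pytest.approx(truth, rel=1e-3), name
        assert fit.residual_rms < 1e-8

    def test_delta_max_from_fit(self):
        y = two_term_exp(ACT_TIMES, **TRUE_PARAMS)
        fit = fit_two_term_exp(_series(y))
        assert delta_max(fit, 2.0) == pytest.approx(-1.09512, abs=1e-3)
        # intermediate evaluation times for steady-state comparisons
        d1 = delta_max(fit, 1.0)
        assert abs(d1) < abs(delta_max(fit, 2.0))

    def test_degenerate_flat_series_fits_constant(self):
        y = np.full(len(ACT_TIMES), -0.7)
        fit = fit_two_term_exp(_series(y))
        assert fit(1.0) == pytest.approx(-0.7, abs=1e-6)
        assert delta_max(fit, 2.0) == pytest.approx(0.0, abs=1e-6)

    def test_slow_tau_beyond_bound_is_clipped_and_flagged(self):
        y = two_term_exp(ACT_TIMES, C=-3.0, m_f=1.0, m_s=2.0,
                         tau_f=0.2, tau_s=100.0)
        fit = fit_two_term_exp(_series(y))
        assert fit.tau_s == pytest.approx(50.0, rel=0.01)
        assert fit.at_bound_tau_s and fit.at_bound

    def test_translation_invariance(self):
        y = two_term_exp(ACT_TIMES, **TRUE_PARAMS)
        f0 = fit_two_term_exp(_series(y))
        f1 = fit_two_term_exp(_series(y + 5.0))
        assert f1.C - f0.C == pytest.approx(5.0, abs=1e-6)
        assert f1.tau_f == pytest.approx(f0.tau_f, rel=1e-6)
        assert f1.tau_s == pytest.approx(f0.tau_s, rel=1e-4)
        assert delta_max(f1, 2.0) == pytest.approx(delta_max(f0, 2.0), abs=1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(ParameterError):
            fit_two_term_exp(_series(np.zeros(5), ACT_TIMES[:5]))

    def test_grid_fitter_matches_exact_solution_on_grid(self):
        """The separable grid projection is exact when taus lie on the grid."""
        y = two_term_exp(ACT_TIMES, C=-1.5, m_f=0.8, m_s=0.7,
                         tau_f=0.2, tau_s=20.0)
        fitted = GridExpFitter(ACT_TIMES).fitted(y)
        assert np.allclose(fitted, y, atol=1e-10)


class TestBaselineTrend:
    BASE_TIMES = np.array([0.025, 0.125, 0.225])

    def test_flat_series(self):
        t = baseline_trend(_series(np.zeros(3), self.BASE_TIMES, "baseline"))
        assert t.slope_db_per_s == 0.0
        assert t.p_value == 1.0

    def test_exact_line_recovers_slope(self):
        t = baseline_trend(
            _series(1.0 * self.BASE_TIMES + 0.3, self.BASE_TIMES, "baseline")
        )
        assert t.slope_db_per_s == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            baseline_trend(_series([0.0, 1.0], self.BASE_TIMES[:2], "baseline"))

    def test_null_rejection_rate_matches_alpha(self):
        """White-noise baselines reject the zero-slope null at ~alpha."""
        rng = np.random.default_rng(17)
        times = np.arange(10) * 0.05
        rejections = sum(
            baseline_trend(_series(rng.normal(size=10), times, "baseline")).p_value
            < 0.05
            for _ in range(400)
        )
        # binomial 95% band around 0.05 * 400 = 20
        assert 11 <= rejections <= 30


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
def test_delta_affine_reference_properties(shift, scale):
    """Scaling magnitudes rescales delta additively; reference stays zero."""
    m = np.array([1.0, 0.9, 0.8, 0.7, 0.75, 0.85]) * 1e-3
    d0 = compute_delta(m, ACT_TIMES[:6], 1000.0, "activation")
    d1 = compute_delta(m * scale, ACT_TIMES[:6], 1000.0, "activation")
    assert np.allclose(d0.delta_db, d1.delta_db, atol=1e-9)
    assert d1.delta_db[0] == 0.0
    del shift
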