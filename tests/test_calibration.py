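import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carbrisk.calibration import (
    BlankSet,
    CalibrationSeries,
    fit_calibration,
    lod_loq,
    quantify,
    relative_response,
)
from carbrisk.simulate import CalibrationSimSpec, generate_calibration_series


def make_series(slope=2.0, intercept=0.0, conc=(1.0, 2.0, 5.0, 10.0),
                medium="solvent", is_area=100.0):
    conc = np.asarray(conc, float)
    rr = slope * conc + intercept
    return CalibrationSeries(conc, rr * is_area, np.full(conc.size, is_area),
                             medium=medium)


class TestRelativeResponse:
    @pytest.mark.parametrize("analyte,is_area,expected",
                             [(100, 100, 1.0), (250, 100, 2.5), (0, 10, 0.0)])
    def test_ratio(self, analyte, is_area, expected):
        assert relative_response(analyte, is_area) == expected

    def test_missing_internal_standard_rejected(self):
        with pytest.raises(ValueError):
            relative_response(50, 0)


class TestFit:
    def test_noiseless_line_recovered_exactly(self):
        curve = fit_calibration(make_series(slope=2.0, intercept=0.0))
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.concentration_range == (1.0, 10.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            CalibrationSeries(np.array([5.0, 5.0, 5.0]),
                              np.array([1.0, 2.0, 3.0]), np.ones(3))

    def test_flat_response_flagged_non_informative(self):
        series = CalibrationSeries(np.array([1.0, 2.0, 5.0]),
                                   np.full(3, 50.0), np.full(3, 100.0))
        curve = fit_calibration(series)
        assert curve.slope == 0.0
        assert not curve.informative

    def test_r_squared_invariant_under_joint_rescaling(self):
        rng = np.random.default_rng(3)
        conc = np.array([0.5, 1, 2, 5, 10, 20.0])
        rr = 1.3 * conc + 0.01 + rng.normal(0, 0.05, conc.size)
        base = CalibrationSeries(conc, rr * 100, np.full(conc.size, 100.0))
        scaled = CalibrationSeries(conc * 7.0, rr * 300, np.full(conc.size, 100.0))
        assert fit_calibration(base).r_squared == pytest.approx(
            fit_calibration(scaled).r_squared, rel=1e-12)

    def test_ols_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        conc = np.array([0.001, 0.01, 0.1, 1, 10, 100.0])
        rr = 0.6 * conc + 0.002 + rng.normal(0, 0.01, conc.size)
        series = CalibrationSeries(conc, rr * 1e5, np.full(conc.size, 1e5))
        curve = fit_calibration(series)
        ref = sm.OLS(series.relative_responses, sm.add_constant(conc)).fit()
        assert curve.slope == pytest.approx(ref.params[1], rel=1e-10)
        assert curve.intercept == pytest.approx(ref.params[0], rel=1e-10)
        assert curve.r_squared == pytest.approx(ref.rsquared, rel=1e-10)

    def test_simulated_noisy_series_recovers_slope_within_3se(self):
        from scipy import stats

        spec = CalibrationSimSpec(true_slope=0.6, noise_sd=0.05, seed=21)
        series = generate_calibration_series(spec, "solvent")
        curve = fit_calibration(series)
        res = stats.linregress(series.concentrations, series.relative_responses)
        assert abs(curve.slope - 0.6) < 3 * res.stderr


class TestQuantify:
    def test_inverts_line(self):
        curve = fit_calibration(make_series(slope=2.0, intercept=0.0))
        assert quantify(curve, 4.0).concentration == pytest.approx(2.0)

    def test_response_at_intercept_is_zero(self):
        curve = fit_calibration(make_series(slope=2.0, intercept=0.5))
        q = quantify(curve, 0.5)
        assert q.concentration == 0.0 and not q.below_range

    def test_negative_backcalculation_clamps_with_flag(self):
        curve = fit_calibration(make_series(slope=2.0, intercept=0.5))
        q = quantify(curve, 0.1)
        assert q.concentration == 0.0 and q.below_range

    def test_extrapolation_flagged(self):
        curve = fit_calibration(make_series(slope=2.0, conc=(1.0, 2.0, 5.0)))
        assert quantify(curve, 2 * 50.0).extrapolated

    def test_zero_slope_rejected(self):
        series = CalibrationSeries(np.array([1.0, 2.0, 5.0]),
                                   np.full(3, 50.0), np.full(3, 100.0))
        with pytest.raises(ValueError):
            quantify(fit_calibration(series), 1.0)

    @given(st.floats(0.1, 100), st.floats(-0.5, 0.5), st.floats(0.01, 400))
    def test_round_trip_noiseless(self, slope, intercept, conc):
        curve = fit_calibration(make_series(slope=slope, intercept=intercept))
        rr = slope * conc + intercept
        assert quantify(curve, rr).concentration == pytest.approx(conc, rel=1e-6)


class TestLodLoq:
    def test_hand_arithmetic(self):
        # two-point blank set whose sample SD is exactly 0.002
        d = 0.002 / np.sqrt(2)
        blanks = BlankSet(np.array([0.001 - d, 0.001 + d]))
        assert blanks.sd_blank == pytest.approx(0.002)
        curve = fit_calibration(make_series(slope=0.6))
        lod, loq = lod_loq(blanks, curve)
        assert lod == pytest.approx(0.01)
        assert loq == pytest.approx(0.1 / 3)

    def test_zero_blank_sd_gives_zero_limits(self):
        blanks = BlankSet(np.full(20, 0.005))
        curve = fit_calibration(make_series(slope=0.6))
        lod, loq = lod_loq(blanks, curve)
        assert lod == pytest.approx(0.0, abs=1e-15)
        assert loq == pytest.approx(0.0, abs=1e-15)

    @given(st.floats(1e-6, 1.0), st.floats(0.0, 0.5),
           st.floats(0.01, 10.0))
    def test_loq_lod_ratio_is_ten_thirds(self, mean, sd, slope):
        rng = np.random.default_rng(0)
        blanks = BlankSet(rng.normal(mean, sd, 20))
        curve = fit_calibration(make_series(slope=slope))
        lod, loq = lod_loq(blanks, curve)
        if lod > 0:
            assert loq / lod == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_minimum_signal_definition(self):
        blanks = BlankSet(np.array([1.0, 2.0, 3.0]))
        assert blanks.minimum_signal(3) == pytest.approx(2.0 + 3 * 1.0)

    def test_literal_variant_uses_mean_blank(self):
        sig = np.array([0.01, 0.01, 0.01, 0.010000001])
        blanks = BlankSet(sig)
        curve = fit_calibration(make_series(slope=0.5))
        lod_lit, _ = lod_loq(blanks, curve, formula="literal")
        assert lod_lit == pytest.approx(3 * blanks.mean_blank / 0.5)

    def test_non_positive_slope_rejected(self):
        blanks = BlankSet(np.array([0.0, 0.1]))
        series = CalibrationSeries(np.array([1.0, 2.0, 5.0]),
                                   np.full(3, 50.0), np.full(3, 100.0))
        with pytest.raises(ValueError):
            lod_loq(blanks, fit_calibration(series))
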