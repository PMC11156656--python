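import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carbrisk import datasets
from carbrisk._rand import substream
from carbrisk.risk import (
    ADULT_PROFILE,
    CHILD_PROFILE,
    DietaryRiskModel,
    ExposureProfile,
    LognormalConcentrationModel,
    cdi,
    fit_lognormal_moments,
    hazard_index,
    hazard_quotient,
    hq_p95_closed_form,
    simulate_hq,
)


class TestMomentFit:
    def test_point_mass(self):
        assert fit_lognormal_moments(math.e, 0.0) == pytest.approx((1.0, 0.0))

    @pytest.mark.parametrize("mean,sd,exp_mu,exp_sigma", [
        (10.33, 5.5, 2.2102, 0.4996),
        (1.48, 1.0, 0.2040, 0.6133),
    ])
    def test_survey_scale_examples(self, mean, sd, exp_mu, exp_sigma):
        mu, sigma = fit_lognormal_moments(mean, sd)
        assert mu == pytest.approx(exp_mu, abs=2e-4)
        assert sigma == pytest.approx(exp_sigma, abs=2e-4)

    @given(st.floats(1e-3, 1e3), st.floats(0.0, 1e3))
    def test_round_trip_moments(self, mean, sd):
        mu, sigma = fit_lognormal_moments(mean, sd)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-10)
        var = math.expm1(sigma**2) * math.exp(2 * mu + sigma**2)
        assert var == pytest.approx(sd**2, rel=1e-8, abs=1e-12)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_moments(0.0, 1.0)

    def test_parameter_recovery_from_draws(self):
        mu, sigma = 2.2102, 0.4996
        rng = substream(31, "recovery-check")
        draws = rng.lognormal(mu, sigma, size=100_000)
        model = LognormalConcentrationModel.from_samples("x", draws)
        assert model.mu == pytest.approx(mu, rel=0.01)
        assert model.sigma == pytest.approx(sigma, rel=0.01)


class TestCdiHq:
    def test_zero_concentration(self):
        assert cdi(0.0, ADULT_PROFILE) == 0.0

    def test_adult_hand_arithmetic(self):
        assert cdi(0.01033, ADULT_PROFILE) == pytest.approx(1.6867e-5, rel=1e-4)

    def test_child_hand_arithmetic(self):
        assert cdi(0.00085, CHILD_PROFILE) == pytest.approx(1.9833e-6, rel=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            cdi(-1.0, ADULT_PROFILE)

    def test_hq_hand_arithmetic(self):
        assert hazard_quotient(1.6867e-5, 0.01) == pytest.approx(1.6867e-3)

    def test_doubling_rfdo_halves_hq(self):
        assert hazard_quotient(1.0, 0.02) == pytest.approx(
            hazard_quotient(1.0, 0.01) / 2)

    def test_non_positive_rfdo_rejected(self):
        with pytest.raises(ValueError):
            hazard_quotient(1.0, 0.0)


class TestSimulateHq:
    def test_point_mass_degenerate(self):
        model = LognormalConcentrationModel("x", 10.0, 0.0)
        s = simulate_hq(model, ADULT_PROFILE, 0.01, n_replicates=100, seed=1)
        assert s.hq_mean == pytest.approx(1.63286e-3, rel=1e-5)
        assert s.hq_p95 == pytest.approx(s.hq_mean)

    def test_p95_matches_closed_form_oracle(self):
        model = LognormalConcentrationModel("x", 1.0, 1.0,
                                            mu=0.0, sigma=1.0)
        s = simulate_hq(model, ADULT_PROFILE, 0.01, n_replicates=100_000, seed=2)
        assert hq_p95_closed_form(model, ADULT_PROFILE, 0.01) == pytest.approx(
            8.4585e-4, rel=1e-3)
        assert s.hq_p95 == pytest.approx(8.4585e-4, rel=0.01)

    def test_child_adult_scaling_with_common_draws(self):
        model = LognormalConcentrationModel("x", 10.33, 5.5)
        rng_a = substream(5, "crn")
        rng_c = substream(5, "crn")
        _, hq_a = simulate_hq(model, ADULT_PROFILE, 0.01, 10_000,
                              rng=rng_a, return_draws=True)
        _, hq_c = simulate_hq(model, CHILD_PROFILE, 0.01, 10_000,
                              rng=rng_c, return_draws=True)
        ratio = (35 / 15) / (114.3 / 70)
        assert ratio == pytest.approx(1.4290, abs=1e-4)
        np.testing.assert_allclose(hq_c, hq_a * ratio, rtol=1e-12)

    def test_deterministic_under_seed(self):
        model = LognormalConcentrationModel("x", 10.33, 5.5)
        a = simulate_hq(model, ADULT_PROFILE, 0.01, 5000, seed=9)
        b = simulate_hq(model, ADULT_PROFILE, 0.01, 5000, seed=9)
        assert a == b

    def test_invalid_replicate_count_rejected(self):
        model = LognormalConcentrationModel("x", 1.0, 0.5)
        with pytest.raises(ValueError):
            simulate_hq(model, ADULT_PROFILE, 0.01, n_replicates=0, seed=1)


class TestClosedForm:
    def test_sigma_zero_equals_deterministic_hq(self):
        model = LognormalConcentrationModel("x", 0.0, 0.0,
                                            mu=math.log(10.0), sigma=0.0)
        assert hq_p95_closed_form(model, ADULT_PROFILE, 0.01) == pytest.approx(
            1.63286e-3, rel=1e-5)

    @given(st.floats(0.01, 1.5), st.floats(0.02, 2.0))
    def test_monotone_in_sigma(self, s1, ds):
        m1 = LognormalConcentrationModel("x", 1, 1, mu=0.0, sigma=s1)
        m2 = LognormalConcentrationModel("x", 1, 1, mu=0.0, sigma=s1 + ds)
        assert (hq_p95_closed_form(m2, ADULT_PROFILE, 0.01)
                > hq_p95_closed_form(m1, ADULT_PROFILE, 0.01))


class TestHazardIndex:
    def test_sum(self):
        assert hazard_index([0.001, 0.002, 0.0]) == pytest.approx(0.003)

    def test_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert hazard_index([]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hazard_index([0.1, -0.2])

    def test_monotone_in_components(self):
        base = [0.001, 0.002]
        assert hazard_index(base + [0.01]) > hazard_index(base)


@pytest.fixture(scope="module")
def fixture_models():
    return [
        LognormalConcentrationModel(r.pesticide, r.mean,
                                    datasets.implied_sd(r, "range"))
        for r in datasets.SURVEY_ROWS if r.pesticide in datasets.RFDO_TABLE
    ]


class TestDietaryRiskModel:
    def test_mc_hi_matches_closed_form_sum(self, fixture_models):
        dm = DietaryRiskModel(fixture_models, datasets.RFDO_TABLE)
        res = dm.fit(n_replicates=100_000, seed=3)
        for profile in (ADULT_PROFILE, CHILD_PROFILE):
            assert res.hazard_index(profile.label) == pytest.approx(
                dm.closed_form_hi(profile), rel=0.02)

    def test_hi_is_sum_of_p95(self, fixture_models):
        dm = DietaryRiskModel(fixture_models, datasets.RFDO_TABLE)
        res = dm.fit(n_replicates=5000, seed=3)
        for label, summaries in res.per_profile.items():
            assert res.hazard_index(label) == pytest.approx(
                sum(s.hq_p95 for s in summaries))

    def test_profile_scaling_of_hi(self, fixture_models):
        dm = DietaryRiskModel(fixture_models, datasets.RFDO_TABLE)
        res = dm.fit(n_replicates=5000, seed=3)
        his = res.hazard_indices
        assert his["child"] / his["adult"] == pytest.approx(
            (35 / 15) / (114.3 / 70), rel=1e-9)

    def test_missing_rfdo_excluded_with_notice(self, fixture_models):
        extra = fixture_models + [LognormalConcentrationModel("aminocarb", 0.6, 0.8)]
        with pytest.warns(UserWarning, match="aminocarb"):
            dm = DietaryRiskModel(extra, datasets.RFDO_TABLE)
        assert dm.excluded == ["aminocarb"]
        assert len(dm.included) == len(fixture_models)

    def test_from_residue_table(self, fixture_bundle, residue_table):
        dm = DietaryRiskModel.from_residue_table(residue_table,
                                                 fixture_bundle.rfdo_table)
        assert {m.pesticide for m in dm.included} <= set(datasets.RFDO_TABLE)
        res = dm.fit(n_replicates=2000, seed=1)
        assert all(hi > 0 for hi in res.hazard_indices.values())

    def test_summary_renders(self, fixture_models):
        dm = DietaryRiskModel(fixture_models, datasets.RFDO_TABLE)
        res = dm.fit(n_replicates=2000, seed=1)
        text = res.summary()
        assert "HI" in text and "adult" in text and "child" in text
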