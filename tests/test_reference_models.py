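"""Reference equations: predictions, z-scores, ranges, effect sizes."""
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulmoref as pr
from pulmoref.exceptions import (
    ApplicabilityWarning,
    InvalidCovariateError,
    InvalidObservationError,
    SchemaError,
)
from pulmoref.reference import classify_d

RAW = pr.Outcome.RAW
EELV = pr.Outcome.EELV

SD_F_250_P2 = pr.CovariateSet(mass_g=250, strain="sprague_dawley", sex="female", peep_cmH2O=2)
W_M_300_P6 = pr.CovariateSet(mass_g=300, strain="wistar", sex="male", peep_cmH2O=6)

ALL_COVS = [
    pr.CovariateSet(mass_g=m, strain=s, sex=x, peep_cmH2O=p)
    for m, s, x, p in [
        (200, "sprague_dawley", "female", 0),
        (317, "sprague_dawley", "male", 3),
        (260, "wistar", "female", 4),
        (310, "wistar", "male", 6),
    ]
]


class TestPredictions:
    def test_mu_raw_hand_value(self, models):
        # 5.36400 - 0.07261*sqrt(250) - 0.36403
        assert models[RAW].mu(SD_F_250_P2) == pytest.approx(3.851905, abs=1e-6)

    def test_mu_reference_category_is_intercept_plus_mass(self, models):
        for mass in (180.0, 250.0, 333.3):
            cov = pr.CovariateSet(mass, "sprague_dawley", "female", 0)
            c = models[RAW].coefficients
            assert models[RAW].mu(cov) == c.a0 + c.a1 * np.sqrt(mass)

    def test_mu_eelv_hand_value(self, models):
        assert models[EELV].mu(W_M_300_P6) == pytest.approx(9.769698, abs=1e-6)

    def test_sigma_raw_has_no_mass_or_sex_term(self, models):
        # exp(-1.17594 - 0.21221) for any mass/sex at PEEP 2
        for cov in (SD_F_250_P2, pr.CovariateSet(700, "sprague_dawley", "male", 2)):
            assert models[RAW].sigma(cov) == pytest.approx(0.249537, abs=1e-6)

    def test_sigma_h_absent_terms_contribute_zero(self, models):
        # H sigma model: intercept + mass + sex only (no strain, no PEEP)
        c = models[pr.Outcome.H].coefficients
        for cov in ALL_COVS:
            expected = np.exp(c.b0 + c.b1 * cov.mass_g + c.b3 * cov.i_male)
            assert models[pr.Outcome.H].sigma(cov) == pytest.approx(expected, rel=1e-12)

    def test_sigma_eelv_hand_value(self, models):
        assert models[EELV].sigma(W_M_300_P6) == pytest.approx(1.66782, abs=1e-4)

    def test_predicted_median_backtransforms(self, models):
        assert models[RAW].predicted_median(SD_F_250_P2) == pytest.approx(47.08, abs=0.05)
        # identity transform for EELV
        assert models[EELV].predicted_median(W_M_300_P6) == models[EELV].mu(W_M_300_P6)

    def test_unknown_peep_rejected(self):
        with pytest.raises(InvalidCovariateError):
            pr.CovariateSet(250, "sprague_dawley", "female", 5)

    def test_mass_outside_range_warns_but_predicts(self, models):
        cov = pr.CovariateSet(900, "sprague_dawley", "male", 2)
        with pytest.warns(ApplicabilityWarning):
            value = models[RAW].mu(cov)
        assert np.isfinite(value)


class TestZScores:
    def test_observed_60_hand_value(self, models):
        res = models[RAW].z_score(SD_F_250_P2, 60.0)
        assert res.z == pytest.approx(0.9716, abs=1e-3)
        assert res.classification == "within_range"

    def test_z_of_predicted_median_is_zero(self, models):
        for outcome, model in models.items():
            for cov in ALL_COVS:
                res = model.z_score(cov, model.predicted_median(cov))
                assert res.z == pytest.approx(0.0, abs=1e-12)
                assert res.percentile == pytest.approx(50.0, abs=1e-9)
                assert res.classification == "within_range"

    def test_z_above_threshold_classified_above_range(self, models):
        m = models[RAW]
        observed = float(np.exp(m.mu(SD_F_250_P2) + 1.70 * m.sigma(SD_F_250_P2)))
        assert m.z_score(SD_F_250_P2, observed).classification == "above_range"

    def test_nonpositive_observed_rejected_for_log_outcome(self, models):
        with pytest.raises(InvalidObservationError):
            models[RAW].z_score(SD_F_250_P2, 0.0)

    def test_percentile_round_trip(self, models):
        from scipy import stats

        m = models[RAW]
        for p in (1.0, 25.0, 50.0, 97.5):
            mu, sigma = m.mu(SD_F_250_P2), m.sigma(SD_F_250_P2)
            observed = float(np.exp(mu + stats.norm.ppf(p / 100) * sigma))
            assert m.z_score(SD_F_250_P2, observed).percentile == pytest.approx(p, abs=1e-9)


class TestNormalRange:
    def test_hand_values(self, models):
        lo, hi = models[RAW].normal_range(SD_F_250_P2, 0.90)
        assert lo == pytest.approx(31.2, abs=0.1)
        assert hi == pytest.approx(71.0, abs=0.1)

    def test_limits_collapse_to_median(self, models):
        lo, hi = models[RAW].normal_range(SD_F_250_P2, 1e-12)
        med = models[RAW].predicted_median(SD_F_250_P2)
        assert lo == pytest.approx(med, rel=1e-6)
        assert hi == pytest.approx(med, rel=1e-6)

    def test_central_95_uses_1_96(self, models):
        m = models[RAW]
        lo, hi = m.normal_range(SD_F_250_P2, 0.95)
        mu, sigma = m.mu(SD_F_250_P2), m.sigma(SD_F_250_P2)
        assert np.log(hi) - mu == pytest.approx(1.959964 * sigma, rel=1e-6)
        assert lo < m.predicted_median(SD_F_250_P2) < hi

    def test_monotone_in_central_mass(self, models):
        widths = []
        for cm in (0.5, 0.8, 0.9, 0.95, 0.99):
            lo, hi = models[EELV].normal_range(W_M_300_P6, cm)
            widths.append(hi - lo)
        assert all(w2 > w1 for w1, w2 in zip(widths, widths[1:]))

    def test_invalid_central_mass(self, models):
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(InvalidCovariateError):
                models[RAW].normal_range(SD_F_250_P2, bad)


class TestEffectSizes:
    def test_g_strain_percent_change(self, models):
        rep = models[pr.Outcome.G].effect_sizes("strain")
        assert rep.percent_change_mu == pytest.approx(-5.56, abs=0.01)

    def test_zero_coefficient_gives_null_effect(self, models):
        doc = json.loads(
            json.dumps(_bundled_document())
        )
        doc["g"]["mu"]["strain_wistar"] = 0.0
        zeroed = pr.load_reference_coefficients(doc)
        rep = zeroed[pr.Outcome.G].effect_sizes("strain")
        assert rep.percent_change_mu == 0.0
        assert rep.d_value == 0.0
        assert rep.d_class == "below_small"

    def test_d_classification_thresholds(self):
        assert classify_d(0.9) == "large"
        assert classify_d(0.1) == "below_small"
        assert classify_d(0.2) == "small"
        assert classify_d(0.5) == "medium"
        assert classify_d(1.3) == "very_large"

    def test_sex_effects_larger_than_strain(self, models):
        # sex is consistently the stronger covariate across outcomes
        for model in models.values():
            assert model.effect_sizes("sex").d_value > model.effect_sizes("strain").d_value


def _bundled_document():
    from importlib import resources

    return json.loads(
        resources.files("pulmoref.data").joinpath("reference_coefficients.json").read_text()
    )


# Every coefficient of the published table, at printed 5-decimal precision.
PRINTED_TABLE = {
    ("raw", "mu"): {"intercept": "5.36400", "sqrt_mass": "-0.07261",
                    "strain_wistar": "-0.07227", "sex_male": "0.24217",
                    "peep": {"0": "0.00000", "1": "-0.20376", "2": "-0.36403",
                             "3": "-0.51259", "4": "-0.65403", "6": "-0.96527"}},
    ("raw", "sigma"): {"intercept": "-1.17594", "strain_wistar": "-0.12428",
                       "peep": {"0": "0.00000", "1": "-0.19736", "2": "-0.21221",
                                "3": "-0.16229", "4": "-0.05226", "6": "0.06301"}},
    ("g", "mu"): {"intercept": "7.87594", "sqrt_mass": "-0.06022",
                  "strain_wistar": "-0.05717", "sex_male": "0.16888",
                  "peep": {"0": "0.00000", "1": "-0.17255", "2": "-0.27962",
                           "3": "-0.36856", "4": "-0.45209", "6": "-0.53716"}},
    ("g", "sigma"): {"intercept": "-1.85751", "sex_male": "0.12800",
                     "peep": {"0": "0.00000", "1": "-0.25486", "2": "-0.29300",
                              "3": "-0.23964", "4": "-0.26472", "6": "-0.32089"}},
    ("h", "mu"): {"intercept": "9.98623", "sqrt_mass": "-0.09948",
                  "strain_wistar": "-0.05654", "sex_male": "0.20138",
                  "peep": {"0": "0.00000", "1": "-0.20777", "2": "-0.39299",
                           "3": "-0.58629", "4": "-0.76092", "6": "-0.98447"}},
    ("h", "sigma"): {"intercept": "-1.89371", "mass": "0.00078", "sex_male": "-0.07682"},
    ("eelv", "mu"): {"intercept": "-5.29284", "sqrt_mass": "0.58809",
                     "strain_wistar": "-0.16721", "sex_male": "-0.27947",
                     "peep": {"0": "0.00000", "1": "0.82506", "2": "1.57536",
                              "3": "2.47960", "4": "3.46782", "6": "5.32320"}},
    ("eelv", "sigma"): {"intercept": "-0.87845", "mass": "0.00413",
                        "strain_wistar": "-0.13945", "sex_male": "-0.41105",
                        "peep": {"0": "0.00000", "1": "0.02265", "2": "0.13399",
                                 "3": "0.27625", "4": "0.45725", "6": "0.70147"}},
}


class TestCoefficientDocument:
    def test_bundled_coefficients_match_printed_table(self):
        doc = _bundled_document()
        for (outcome, block), expected in PRINTED_TABLE.items():
            got = doc[outcome][block]
            assert set(got) == set(expected), (outcome, block)
            for key, val in expected.items():
                if key == "peep":
                    assert {k: f"{v:.5f}" for k, v in got["peep"].items()} == val
                else:
                    assert f"{got[key]:.5f}" == val, (outcome, block, key)

    def test_bundled_raw_intercept(self, models):
        assert models[RAW].coefficients.a0 == 5.36400

    def test_absent_term_flagged_and_contributes_zero(self, models):
        c = models[RAW].coefficients
        assert c.b1 is None and c.b3 is None
        # sigma identical across sexes and masses
        a = models[RAW].sigma(pr.CovariateSet(200, "sprague_dawley", "female", 0))
        b = models[RAW].sigma(pr.CovariateSet(600, "sprague_dawley", "male", 0))
        assert a == b

    def test_unknown_outcome_rejected(self):
        with pytest.raises(SchemaError):
            pr.load_reference_coefficients({"fev1": {"mu": {}, "sigma": {}}})

    def test_missing_keys_named(self):
        doc = _bundled_document()
        del doc["raw"]["mu"]["sqrt_mass"]
        with pytest.raises(SchemaError) as err:
            pr.load_reference_coefficients(doc)
        assert "sqrt_mass" in str(err.value)

    def test_round_trip_through_document(self, models, tmp_path):
        path = tmp_path / "coefs.json"
        path.write_text(json.dumps(_bundled_document()))
        reloaded = pr.load_reference_coefficients(path)
        for outcome in pr.Outcome:
            assert reloaded[outcome].coefficients == models[outcome].coefficients


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    mass=st.floats(1.0, 2000.0),
    strain=st.sampled_from(["sprague_dawley", "wistar"]),
    sex=st.sampled_from(["female", "male"]),
    peep=st.sampled_from([0, 1, 2, 3, 4, 6]),
    outcome=st.sampled_from(list(pr.Outcome)),
)
def test_sigma_always_positive(mass, strain, sex, peep, outcome):
    """The log link guarantees sigma > 0 for every covariate combination."""
    import warnings

    models = pr.default_models()
    cov = pr.CovariateSet(mass, strain, sex, peep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ApplicabilityWarning)
        assert models[outcome].sigma(cov) > 0
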