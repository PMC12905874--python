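"""Parameter loading, distribution fitting, and derived-quantity transforms."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from hfcea import (
    ParameterSet,
    ParameterValidationError,
    fit_beta,
    fit_gamma,
    hr_to_probability,
    inflate_cost,
    intervention_adherence,
    load_parameter_set,
)
from hfcea.parameters import TABLE_NAMES, Z95_WIDTH, sampling_check

# table rows frozen from the published parameter table
TABLE1_BASES = {
    "p_good_adherence_usual": 0.556,
    "adherence_gain": 0.185,
    "p_exac_good": 0.232,
    "p_exac_poor": 0.419,
    "p_survive_exac": 0.597,
    "p_worsen": 0.150,
    "p_survive_no_exac": 0.865,
    "u_exacerbation": 0.560,
    "u_stable": 0.780,
    "u_worsened": 0.600,
    "cost_intervention_year1": 498.0,
    "cost_intervention_subsequent": 400.0,
    "cost_hospitalization": 33851.0,
    "cost_outpatient": 1304.0,
    "cost_ed_visit": 1997.0,
    "cost_hf_medications": 367.0,
    "cost_worsening_medications": 2893.0,
    "cost_post_acute": 4538.0,
}


def mom_beta(mean, low, high):
    """Independent method-of-moments oracle for the beta fit."""
    var = ((high - low) / Z95_WIDTH) ** 2
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def mom_gamma(mean, low, high):
    var = ((high - low) / Z95_WIDTH) ** 2
    return mean**2 / var, var / mean


class TestFitBeta:
    def test_matches_moment_oracle_and_sampling(self):
        d = fit_beta(0.232, 0.174, 0.289)
        a, b = mom_beta(0.232, 0.174, 0.289)
        assert d.family == "beta"
        assert d.shape_a == pytest.approx(a, rel=1e-12)
        assert d.shape_b_or_scale == pytest.approx(b, rel=1e-12)
        assert d.mean() == pytest.approx(0.232, rel=1e-6)
        sample_mean, se = sampling_check(d, n=1_000_000, seed=11)
        assert abs(sample_mean - 0.232) < 3 * se

    def test_zero_width_range_is_point_mass(self):
        d = fit_beta(0.5, 0.5, 0.5)
        assert d.family == "point_mass"
        assert d.mean() == 0.5

    def test_too_wide_range_rejected_by_name(self):
        with pytest.raises(ParameterValidationError, match="narrow"):
            fit_beta(0.05, 0.0, 1.0, name="narrow")

    @given(
        mean=st.floats(0.2, 0.8),
        half_width=st.floats(0.01, 0.15),
    )
    @settings(max_examples=50, deadline=None)
    def test_fitted_mean_equals_input_mean(self, mean, half_width):
        low, high = max(mean - half_width, 0.0), min(mean + half_width, 1.0)
        d = fit_beta(mean, low, high)
        assert d.mean() == pytest.approx(mean, rel=1e-6)


class TestFitGamma:
    @pytest.mark.parametrize(
        "mean, low, high",
        [(33851.0, 6603.0, 73382.0), (498.0, 373.0, 622.0)],
    )
    def test_matches_moment_oracle(self, mean, low, high):
        d = fit_gamma(mean, low, high)
        shape, scale = mom_gamma(mean, low, high)
        assert d.family == "gamma"
        assert d.shape_a == pytest.approx(shape, rel=1e-12)
        assert d.shape_b_or_scale == pytest.approx(scale, rel=1e-12)
        assert d.mean() == pytest.approx(mean, rel=1e-6)

    def test_sampling_cross_check(self):
        d = fit_gamma(33851.0, 6603.0, 73382.0)
        sample_mean, se = sampling_check(d, n=1_000_000, seed=7)
        assert abs(sample_mean - 33851.0) < 3 * se

    def test_nonpositive_low_rejected(self):
        with pytest.raises(ParameterValidationError):
            fit_gamma(100.0, 0.0, 200.0)


class TestDerivedQuantities:
    def test_hazard_ratio_reproduces_poor_adherence_probability(self):
        # 0.232 x 1.81 = 0.41992; the table prints this as 0.419
        p = hr_to_probability(0.232, 1.81)
        assert p == pytest.approx(0.41992)
        assert abs(p - 0.419) < 1e-3

    @given(p=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_identity_ratio(self, p):
        assert hr_to_probability(p, 1.0) == p

    def test_probability_ceiling(self):
        assert hr_to_probability(0.9, 1.81) == 1.0

    @given(
        p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0),
        hr1=st.floats(0.1, 5.0), hr2=st.floats(0.1, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, p1, p2, hr1, hr2):
        lo_p, hi_p = sorted([p1, p2])
        lo_h, hi_h = sorted([hr1, hr2])
        assert hr_to_probability(lo_p, lo_h) <= hr_to_probability(hi_p, lo_h)
        assert hr_to_probability(lo_p, lo_h) <= hr_to_probability(lo_p, hi_h)
        assert 0.0 <= hr_to_probability(p1, hr1) <= 1.0

    @pytest.mark.parametrize(
        "p, gain, expected",
        [(0.556, 0.185, 0.741), (0.556, 0.0, 0.556), (0.95, 0.185, 1.0)],
    )
    def test_intervention_adherence(self, p, gain, expected):
        assert intervention_adherence(p, gain) == pytest.approx(expected)

    def test_cpi_adjustment(self):
        assert inflate_cost(100.0, 250.0, 250.0) == 100.0
        assert inflate_cost(100.0, 200.0, 300.0) == 150.0
        round_trip = inflate_cost(inflate_cost(33851.0, 237.0, 310.5), 310.5, 237.0)
        assert round_trip == pytest.approx(33851.0, abs=1e-9)
        with pytest.raises(ParameterValidationError):
            inflate_cost(100.0, 0.0, 200.0)


class TestParameterSet:
    def test_bundled_defaults_reproduce_published_table(self, params):
        assert set(params.specs) == set(TABLE_NAMES)
        for name, base in TABLE1_BASES.items():
            assert params[name] == pytest.approx(base), name
        assert params["wtp_threshold"] == 150_000
        assert params["hazard_ratio_nonadherent"] == 1.81
        assert params["n_psa_iterations"] == 1000

    def test_fitted_means_match_bases(self, params):
        for name, dist in params.fitted().items():
            assert dist.mean() == pytest.approx(params[name], rel=1e-6), name

    def test_round_trip_is_lossless(self, params, tmp_path):
        out = tmp_path / "params.yaml"
        params.to_yaml(out)
        reloaded = load_parameter_set(out)
        assert reloaded.to_dict() == params.to_dict()

    def test_missing_parameter_named_in_error(self, params, tmp_path):
        payload = params.to_dict()
        payload["parameters"] = [
            r for r in payload["parameters"] if r["name"] != "cost_hospitalization"
        ]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(payload))
        with pytest.raises(ParameterValidationError, match="cost_hospitalization"):
            load_parameter_set(bad)

    def test_low_above_base_rejected(self, params, tmp_path):
        payload = params.to_dict()
        for row in payload["parameters"]:
            if row["name"] == "p_worsen":
                row["low"] = row["base"] + 0.1
                row["high"] = row["base"] + 0.2
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(payload))
        with pytest.raises(ParameterValidationError, match="p_worsen"):
            load_parameter_set(bad)

    def test_unknown_family_rejected(self, params):
        payload = params.to_dict()
        payload["parameters"][0]["family"] = "lognormal"
        with pytest.raises(ParameterValidationError):
            ParameterSet.from_dict(payload)
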