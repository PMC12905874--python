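"""Tree enumeration, QALY accrual, arm expectations, and the CE comparison."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfcea import (
    Arm,
    ArmResult,
    TimingAssumptions,
    TreePath,
    UtilitySet,
    compare,
    enumerate_paths,
    evaluate_arm,
    make_arms,
    path_qaly,
    scale_to_population,
)
from hfcea.tree_model import PATHS


def test_exactly_ten_valid_paths_per_arm(arms, params):
    intervention, usual = arms
    for arm in arms:
        paths = enumerate_paths(arm, params)
        assert len(paths) == 10
        assert len({p.path_id for p, _ in paths}) == 10


def test_invalid_path_shapes_rejected():
    with pytest.raises(ValueError):
        TreePath("good", False, True, "worsened")  # worsened needs an exacerbation
    with pytest.raises(ValueError):
        TreePath("poor", True, False, "stable")  # decedents end dead


def test_path_probability_is_branch_product(arms, params):
    _, usual = arms
    probs = {p.path_id: pr for p, pr in enumerate_paths(usual, params)}
    # good adherence, no exacerbation, survive: 0.556 x 0.768 x 0.865
    assert probs["good/no_exac/stable"] == pytest.approx(0.556 * 0.768 * 0.865, rel=1e-12)


def test_path_probabilities_sum_to_one(arms, params):
    for arm in arms:
        total = sum(pr for _, pr in enumerate_paths(arm, params))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_intervention_good_adherence_mass(arms, params):
    intervention, _ = arms
    good = sum(pr for p, pr in enumerate_paths(intervention, params) if p.adherence == "good")
    assert good == pytest.approx(0.741, abs=1e-12)


class TestPathQaly:
    utilities = UtilitySet(0.560, 0.780, 0.600)

    def test_stable_full_year(self):
        path = TreePath("good", False, True, "stable")
        assert path_qaly(path, self.utilities) == pytest.approx(0.780)

    @pytest.mark.parametrize("exac", [True, False])
    def test_decedents_accrue_half_year_at_stable_utility(self, exac):
        path = TreePath("poor", exac, False, "dead")
        assert path_qaly(path, self.utilities) == pytest.approx(0.5 * 0.780)

    def test_exacerbation_month_then_destination(self):
        recovered = TreePath("good", True, True, "recovered_stable")
        assert path_qaly(recovered, self.utilities) == pytest.approx(
            (1 / 12) * 0.560 + (11 / 12) * 0.780
        )
        worsened = TreePath("good", True, True, "worsened")
        assert path_qaly(worsened, self.utilities) == pytest.approx(
            (1 / 12) * 0.560 + (11 / 12) * 0.600
        )

    def test_alternative_decedent_conventions(self):
        path = TreePath("good", True, False, "dead")
        t = TimingAssumptions(decedent_utility_convention="exac_then_stable")
        assert path_qaly(path, self.utilities, t) == pytest.approx(
            (1 / 12) * 0.560 + (0.5 - 1 / 12) * 0.780
        )
        t = TimingAssumptions(decedent_utility_convention="exac_then_worsened")
        assert path_qaly(path, self.utilities, t) == pytest.approx(
            (1 / 12) * 0.560 + (0.5 - 1 / 12) * 0.600
        )

    def test_every_path_qaly_within_one_modelled_year(self, params):
        for path in PATHS:
            q = path_qaly(path, self.utilities)
            assert 0.0 <= q <= 1.0


class TestArmExpectations:
    def test_published_expected_qalys(self, arms, params):
        intervention, usual = arms
        assert round(evaluate_arm(usual, params).expected_qaly, 3) == 0.686
        assert round(evaluate_arm(intervention, params).expected_qaly, 3) == 0.691

    def test_no_effect_identity(self, params):
        values = dict(params.base_values())
        values["adherence_gain"] = 0.0
        values["cost_intervention_year1"] = 0.0
        intervention, usual = make_arms(values)
        ri = evaluate_arm(intervention, values)
        ru = evaluate_arm(usual, values)
        assert ri.expected_qaly == pytest.approx(ru.expected_qaly, abs=1e-15)
        assert ri.expected_cost == pytest.approx(ru.expected_cost, abs=1e-12)

    @given(bump=st.floats(0.0, 0.2))
    @settings(max_examples=25, deadline=None)
    def test_expected_qaly_monotone_in_each_utility(self, params, bump):
        base_vals = params.base_values()
        _, usual = make_arms(base_vals)
        q0 = evaluate_arm(usual, base_vals).expected_qaly
        for u in ("u_exacerbation", "u_stable", "u_worsened"):
            vals = dict(base_vals)
            vals[u] = min(vals[u] + bump, 1.0)
            assert evaluate_arm(usual, vals).expected_qaly >= q0 - 1e-15

    @pytest.mark.parametrize("p_usual", [0.3, 0.417, 0.556, 0.7])
    def test_delta_qaly_invariant_to_baseline_adherence(self, params, p_usual):
        # dQALY = gain x (Q_good - Q_poor): the usual-care level cancels
        vals = dict(params.base_values())
        vals["p_good_adherence_usual"] = p_usual
        intervention, usual = make_arms(vals)
        dq = (
            evaluate_arm(intervention, vals).expected_qaly
            - evaluate_arm(usual, vals).expected_qaly
        )
        assert dq == pytest.approx(0.0045057, abs=1e-6)

    def test_delta_qaly_monotone_in_adherence_gain(self, params):
        deltas = []
        for gain in (0.093, 0.185, 0.278):
            vals = dict(params.base_values())
            vals["adherence_gain"] = gain
            intervention, usual = make_arms(vals)
            deltas.append(
                evaluate_arm(intervention, vals).expected_qaly
                - evaluate_arm(usual, vals).expected_qaly
            )
        assert deltas[0] < deltas[1] < deltas[2]


class TestComparison:
    def test_base_case_is_dominant(self, arms, params, schedule):
        intervention, usual = arms
        ce = compare(
            evaluate_arm(intervention, params, schedule=schedule),
            evaluate_arm(usual, params, schedule=schedule),
        )
        assert round(ce.delta_qaly, 4) == 0.0045
        assert ce.quadrant == "SE" and ce.dominant
        assert ce.icer is None

    def test_cost_dominance_without_icer(self):
        ce = compare(ArmResult("intervention", 99.0, 1.0), ArmResult("usual_care", 100.0, 1.0))
        assert ce.delta_qaly == 0.0 and ce.icer is None and not ce.dominant
        assert "cost-dominant" in ce.boundary_note

    def test_icer_at_wtp_boundary_is_cost_effective(self):
        ce = compare(
            ArmResult("intervention", 1500.0, 1.01),
            ArmResult("usual_care", 0.0, 1.0),
            wtp=150_000.0,
        )
        assert ce.quadrant == "NE"
        assert ce.icer == pytest.approx(150_000.0)
        assert ce.cost_effective and not ce.dominant

    def test_dominated_quadrant(self):
        ce = compare(ArmResult("intervention", 100.0, 0.9), ArmResult("usual_care", 0.0, 1.0))
        assert ce.quadrant == "NW" and not ce.cost_effective and ce.icer is None


class TestPopulationScaling:
    def test_hundred_patients(self, arms, params, schedule):
        intervention, usual = arms
        ce = compare(
            evaluate_arm(intervention, params, schedule=schedule),
            evaluate_arm(usual, params, schedule=schedule),
        )
        qalys, savings = scale_to_population(ce, 100)
        assert round(qalys, 2) == 0.45
        assert savings == pytest.approx(100 * abs(ce.delta_cost))
        assert abs(savings - 195_000) < 1000  # printed as $195 thousand

    def test_zero_population(self, arms, params, schedule):
        intervention, usual = arms
        ce = compare(
            evaluate_arm(intervention, params, schedule=schedule),
            evaluate_arm(usual, params, schedule=schedule),
        )
        assert scale_to_population(ce, 0) == (0.0, 0.0)
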