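"""Decision-tree pathway: branch weights, constraint effects, presets."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capacity_cea import (
    ConstraintScenario,
    DiscountSpec,
    InvalidParameterError,
    evaluate_pathway,
    pathway_weights,
    scenario_presets,
)
from capacity_cea import TestingParameters as ScreeningParams


class TestWeights:
    def test_fully_centralized_puts_no_mass_on_local_branches(self, test_params):
        w = pathway_weights(ConstraintScenario(name="x", beta=0.0), test_params)
        assert all(v == 0.0 for (site, _, _), v in w.items() if site == "localized")

    def test_localized_true_positive_weight_is_branch_product(self, test_params):
        scn = ConstraintScenario(name="x", beta=0.11)
        w = pathway_weights(scn, test_params)
        expected = 0.11 * test_params.alk_prevalence * test_params.ihc_sensitivity
        assert w[("localized", "positive", "positive")] == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        beta=st.floats(0.0, 1.0),
        theta=st.floats(0.0, 1.0),
        sens=st.floats(0.0, 1.0),
        spec=st.floats(0.0, 1.0),
    )
    def test_weights_form_probability_distribution(self, beta, theta, sens, spec):
        test = ScreeningParams(
            alk_prevalence=theta, ihc_sensitivity=sens, ihc_specificity=spec
        )
        w = pathway_weights(ConstraintScenario(name="x", beta=beta), test)
        assert all(v >= 0 for v in w.values())
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)


class TestScenarioValidation:
    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ConstraintScenario(name="x", alpha=1.2)
        with pytest.raises(InvalidParameterError):
            ConstraintScenario(name="x", gamma=2)
        with pytest.raises(InvalidParameterError):
            ConstraintScenario(name="x", m_os=0.0)

    def test_local_ihc_cost_is_uplifted_central_cost(self, test_params):
        assert test_params.ihc_cost_local == pytest.approx(29.25, abs=1e-12)

    def test_delay_qaly_loss_arithmetic(self, test_params):
        assert test_params.delay_qaly_loss == pytest.approx(0.03 * 9 / 365, abs=1e-15)
        assert test_params.delay_qaly_loss == pytest.approx(0.000739726, abs=1e-9)


class TestEvaluatePathway:
    def test_constraints_off_equals_unconstrained_baseline(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        base = evaluate_pathway(
            ConstraintScenario(name="baseline"),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        off = evaluate_pathway(
            ConstraintScenario(name="off", alpha=1.0, beta=0.0, gamma=1),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        assert off.delta_cost == base.delta_cost
        assert off.delta_qalys == base.delta_qalys

    def test_alpha_only_changes_access_not_per_patient_outcomes(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        outs = [
            evaluate_pathway(
                ConstraintScenario(name="a", alpha=a),
                test_params, crizotinib_arm, docetaxel_arm, discount,
            )
            for a in (1.0, 0.5, 0.23)
        ]
        assert outs[0].delta_cost == outs[1].delta_cost == outs[2].delta_cost
        assert outs[0].delta_qalys == outs[1].delta_qalys == outs[2].delta_qalys
        assert [o.access_proportion for o in outs] == [1.0, 0.5, 0.23]

    def test_localization_with_full_staffing_adds_exact_test_cost(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        """With gamma=1 the only localization effect is the IHC price delta."""
        base = evaluate_pathway(
            ConstraintScenario(name="b", beta=0.0, gamma=1),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        for beta in (0.11, 0.5, 1.0):
            loc = evaluate_pathway(
                ConstraintScenario(name="b", beta=beta, gamma=1),
                test_params, crizotinib_arm, docetaxel_arm, discount,
            )
            assert loc.delta_cost - base.delta_cost == pytest.approx(
                beta * 4.25, abs=1e-10
            )
            assert loc.delta_qalys == base.delta_qalys

    def test_understaffing_worsens_qalys_and_cost_effectiveness(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        """Survival degradation trims both QALYs and drug-time costs; the
        economically meaningful direction is a strictly worse ICER and NMB."""
        staffed = evaluate_pathway(
            ConstraintScenario(name="s", beta=1.0, gamma=1),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        constrained = evaluate_pathway(
            ConstraintScenario(name="s", beta=1.0, gamma=0),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        assert constrained.delta_qalys < staffed.delta_qalys
        assert (constrained.delta_cost / constrained.delta_qalys
                > staffed.delta_cost / staffed.delta_qalys)
        nmb = lambda o: 50_000.0 * o.delta_qalys - o.delta_cost
        assert nmb(constrained) < nmb(staffed)

    def test_understaffing_delay_penalties_raise_centralized_costs(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        """Fully centralized testing: gamma=0 adds only delay penalties,
        which are non-negative on both the cost and QALY side."""
        staffed = evaluate_pathway(
            ConstraintScenario(name="c", beta=0.0, gamma=1),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        constrained = evaluate_pathway(
            ConstraintScenario(name="c", beta=0.0, gamma=0),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        assert constrained.delta_qalys < staffed.delta_qalys
        assert constrained.delta_cost > staffed.delta_cost

    def test_qalys_non_increasing_in_beta_under_understaffing(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        qalys = [
            evaluate_pathway(
                ConstraintScenario(name="m", beta=b, gamma=0),
                test_params, crizotinib_arm, docetaxel_arm, discount,
            ).delta_qalys
            for b in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))

    def test_delay_scope_flag_widens_the_charged_population(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        treated = evaluate_pathway(
            ConstraintScenario(name="d", beta=0.0, gamma=0),
            test_params, crizotinib_arm, docetaxel_arm, discount,
            delay_applies_to="treated",
        )
        everyone = evaluate_pathway(
            ConstraintScenario(name="d", beta=0.0, gamma=0),
            test_params, crizotinib_arm, docetaxel_arm, discount,
            delay_applies_to="all_tested",
        )
        assert everyone.delta_cost > treated.delta_cost
        assert everyone.delta_qalys < treated.delta_qalys
        with pytest.raises(InvalidParameterError):
            evaluate_pathway(
                ConstraintScenario(name="d"), test_params, crizotinib_arm,
                docetaxel_arm, discount, delay_applies_to="nobody",
            )

    def test_inverted_arm_effectiveness_warns_but_runs(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        with pytest.warns(UserWarning):
            evaluate_pathway(
                ConstraintScenario(name="w"),
                test_params, docetaxel_arm,  # arms swapped on purpose
                crizotinib_arm, discount,
            )

    def test_treated_fraction_is_confirmed_true_positives(
        self, test_params, crizotinib_arm, docetaxel_arm, discount
    ):
        out = evaluate_pathway(
            ConstraintScenario(name="t"),
            test_params, crizotinib_arm, docetaxel_arm, discount,
        )
        assert out.treated_fraction == pytest.approx(
            test_params.alk_prevalence * test_params.ihc_sensitivity, abs=1e-15
        )


class TestPresets:
    def test_five_presets_with_printed_constraint_values(self):
        presets = {p.name: p for p in scenario_presets()}
        assert set(presets) == {
            "baseline", "awareness", "localization", "pathology", "combined"
        }
        assert presets["baseline"].alpha == 1.0 and presets["baseline"].gamma == 1
        assert presets["awareness"].alpha == 0.23
        assert presets["localization"].beta == 0.11
        assert presets["pathology"].gamma == 0
        assert (presets["combined"].alpha, presets["combined"].beta,
                presets["combined"].gamma) == (0.23, 0.11, 0)

    def test_pathology_endpoint_resolved_by_nmb_comparison(
        self, fixture, discount
    ):
        presets = {p.name: p for p in scenario_presets(
            fixture.test, fixture.crizotinib, fixture.docetaxel, discount
        )}
        beta = presets["pathology"].beta
        assert beta in (0.0, 1.0)
        # on the calibrated fixture centralized testing delivers more NMB
        assert beta == 0.0
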