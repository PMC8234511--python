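"""Net benefit, decision curves and classification tables."""

import numpy as np
import pandas as pd
import pytest

import postaki as pk
from postaki.decision import (
    DecisionStrategy,
    classification_table,
    decision_curve,
    default_threshold_grid,
    exchange_rate,
    net_benefit,
)
from postaki.registry import ModelSpec, Term


def make_cohort(risks, outcomes, **cols):
    df = pd.DataFrame({"risk_logit": np.log(np.asarray(risks) / (1 - np.asarray(risks))),
                       "outcome": np.asarray(outcomes, int)})
    for k, v in cols.items():
        df[k] = v
    return df


LOGIT_MODEL = ModelSpec(
    name="identity",
    outcome_label="outcome",
    intercept=0.0,
    terms=(Term("risk_logit", "continuous", coefficient=1.0),),
)


class TestExchangeRate:
    def test_trial_threshold(self):
        assert exchange_rate(0.1) == pytest.approx(9.0)

    def test_symmetric_and_thirty_percent(self):
        assert exchange_rate(0.5) == pytest.approx(1.0)
        assert exchange_rate(0.3) == pytest.approx(7 / 3)

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.2, 1.5])
    def test_boundaries_error(self, t):
        with pytest.raises(ValueError):
            exchange_rate(t)


class TestNetBenefit:
    def test_treat_none_is_zero(self):
        cohort = make_cohort([0.1, 0.9], [0, 1])
        for t in (0.05, 0.3, 0.8):
            assert net_benefit(DecisionStrategy.from_rule("treat_none"), cohort, t, "outcome") == 0.0

    def test_hand_formula_tp10_fp20(self):
        # 100 subjects: strategy treats 30 (10 events, 20 non-events)
        risks = [0.9] * 30 + [0.01] * 70
        outcomes = [1] * 10 + [0] * 20 + [1] * 10 + [0] * 60
        cohort = make_cohort(risks, outcomes)
        nb = net_benefit(DecisionStrategy.from_model(LOGIT_MODEL), cohort, 0.1, "outcome")
        assert nb == pytest.approx(0.1 - 0.2 * (0.1 / 0.9))

    def test_treat_all_at_prevalence_point_two(self):
        cohort = make_cohort([0.5] * 100, [1] * 20 + [0] * 80)
        nb = net_benefit(DecisionStrategy.from_rule("treat_all"), cohort, 0.1, "outcome")
        assert nb == pytest.approx(0.2 - 0.8 / 9)

    def test_treat_all_is_zero_at_threshold_equal_prevalence(self):
        cohort = make_cohort([0.5] * 100, [1] * 20 + [0] * 80)
        nb = net_benefit(DecisionStrategy.from_rule("treat_all"), cohort, 0.2, "outcome")
        assert nb == pytest.approx(0.0, abs=1e-12)

    def test_threshold_outside_unit_interval_errors(self):
        cohort = make_cohort([0.5], [1])
        with pytest.raises(ValueError):
            net_benefit(DecisionStrategy.from_rule("treat_all"), cohort, 1.0, "outcome")

    def test_net_benefit_bounded_by_prevalence(self, grampian_cohort):
        config, cohort = grampian_cohort
        prevalence = cohort[config.true_model.outcome_label].mean()
        strategies = [
            DecisionStrategy.from_model(config.true_model),
            DecisionStrategy.from_rule("any_aki"),
            DecisionStrategy.from_rule("treat_all"),
            DecisionStrategy.from_rule("discharge_egfr_lt_30"),
        ]
        for strat in strategies:
            for t in (0.05, 0.11, 0.3):
                assert net_benefit(strat, cohort, t, config.true_model.outcome_label) <= prevalence + 1e-12


class TestClassificationTable:
    def test_treat_all_and_treat_none_tables(self):
        cohort = make_cohort([0.5] * 100, [1] * 20 + [0] * 80)
        all_t = classification_table(DecisionStrategy.from_rule("treat_all"), cohort, 0.3, "outcome")
        assert (all_t.tp, all_t.fp, all_t.tn, all_t.fn) == (20, 80, 0, 0)
        assert all_t.percent_correct == pytest.approx(20.0)
        none_t = classification_table(DecisionStrategy.from_rule("treat_none"), cohort, 0.3, "outcome")
        assert (none_t.tp, none_t.fp, none_t.tn, none_t.fn) == (0, 0, 80, 20)
        assert none_t.percent_correct == pytest.approx(80.0)

    def test_model_strategy_matches_manual_2x2(self):
        risks = [0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95]
        outcomes = [0, 0, 1, 0, 0, 1, 0, 1, 1, 1]
        cohort = make_cohort(risks, outcomes)
        ct = classification_table(DecisionStrategy.from_model(LOGIT_MODEL), cohort, 0.3, "outcome")
        # treated: risks >= 0.3 -> 7 subjects, of which events: 0.35?no,0.55,0.75,0.85,0.95 -> 4
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (4, 3, 2, 1)
        assert ct.n == 10
        assert ct.to_frame().loc[1, "treated"] == 4

    def test_counts_consistent_with_net_benefit_formula(self, grampian_cohort):
        """2x2-derived net benefit equals the direct formula on the full grid."""
        config, cohort = grampian_cohort
        outcome = config.true_model.outcome_label
        strategies = [
            DecisionStrategy.from_model(config.true_model),
            DecisionStrategy.from_rule("any_aki"),
            DecisionStrategy.from_rule("aki_stage_2_or_3"),
            DecisionStrategy.from_rule("treat_all"),
            DecisionStrategy.from_rule("treat_none"),
            DecisionStrategy.from_rule("discharge_egfr_lt_30"),
        ]
        sub = cohort.head(1500)
        curve = decision_curve(strategies, sub, outcome)
        for strat in strategies:
            for i, t in enumerate(curve.thresholds):
                ct = classification_table(strat, sub, t, outcome)
                direct = ct.tp / ct.n - (ct.fp / ct.n) * t / (1 - t)
                assert curve.series[strat.label][i] == pytest.approx(direct, abs=1e-12)


class TestDecisionCurve:
    def test_two_point_example(self):
        cohort = make_cohort([0.5] * 100, [1] * 20 + [0] * 80)
        curve = decision_curve(
            [DecisionStrategy.from_rule("treat_none"), DecisionStrategy.from_rule("treat_all")],
            cohort, "outcome", thresholds=[0.1],
        )
        assert curve.series["treat_none"][0] == 0.0
        assert curve.series["treat_all"][0] == pytest.approx(0.2 - 0.8 / 9)

    def test_perfect_model_dominates_everywhere(self):
        rng = np.random.default_rng(5)
        outcomes = rng.integers(0, 2, 400)
        risks = np.clip(outcomes.astype(float), 1e-6, 1 - 1e-6)
        cohort = make_cohort(risks, outcomes, aki_stage=rng.integers(0, 4, 400))
        strategies = [
            DecisionStrategy.from_model(LOGIT_MODEL, "perfect"),
            DecisionStrategy.from_rule("treat_all"),
            DecisionStrategy.from_rule("any_aki"),
        ]
        curve = decision_curve(strategies, cohort, "outcome")
        perfect = curve.series["perfect"]
        for label in ("treat_all", "any_aki"):
            assert (perfect >= curve.series[label] - 1e-12).all()

    def test_empty_strategy_list_errors(self):
        with pytest.raises(ValueError):
            decision_curve([], make_cohort([0.5], [1]), "outcome")

    def test_default_grid_covers_prespecified_thresholds(self):
        grid = default_threshold_grid()
        for t in (0.01, 0.10, 0.30, 0.50):
            assert np.isclose(grid, t).any()

    def test_plot_smoke(self, tmp_path):
        cohort = make_cohort([0.5] * 50, [1] * 10 + [0] * 40)
        curve = decision_curve(
            [DecisionStrategy.from_rule("treat_all"), DecisionStrategy.from_rule("treat_none")],
            cohort, "outcome",
        )
        ax = pk.plot_decision_curve(curve, ylim_floor=-0.05)
        ax.figure.savefig(tmp_path / "dca.png")
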