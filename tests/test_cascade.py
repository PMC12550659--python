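"""Cohort cascade ledger, Markov cross-check and scenario comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treatcascade import (
    CascadeConfig,
    NonConvergenceError,
    ResponseSchedule,
    Rounding,
    ScheduleKind,
    build_schedule,
    compare_scenarios,
    cumulative_response_curve,
    markov_expected_treatments,
    run_cascade,
)

schedules_strategy = st.lists(
    st.floats(0.05, 0.95), min_size=1, max_size=30
).map(lambda ps: ResponseSchedule(probs=tuple(ps)))


class TestRunCascade:
    def test_constant_42_reaches_99pct_in_9_cycles_237_treatments(self, constant42):
        res = run_cascade(constant42, CascadeConfig())
        assert res.n_steps == 9
        assert res.total_treatments == 237
        assert round(res.steps[2].cumulative_response_pct) == 80

    def test_declining_schedule_needs_14_steps_230_treatments(self, declining):
        res = run_cascade(declining, CascadeConfig())
        assert res.n_steps == 14
        assert res.total_treatments == 230
        assert res.excess_treatments == 130
        assert round(res.steps[2].cumulative_response_pct) == 84

    def test_certain_first_treatment_means_no_excess(self):
        sched = ResponseSchedule(probs=(1.0,))
        res = run_cascade(sched, CascadeConfig())
        assert res.n_steps == 1
        assert res.total_treatments == 100
        assert res.excess_treatments == 0

    @pytest.mark.parametrize(
        "edit, expected_excess",
        [
            # first step boosted to 57%, later steps unchanged
            (lambda probs: (0.57,) + probs[1:], 110),
            # step 3 restored to first-treatment effectiveness
            (lambda probs: probs[:2] + (0.50,) + probs[3:], 121),
        ],
    )
    def test_step_edited_scenarios(self, declining, edit, expected_excess):
        sched = declining.with_probs(edit(declining.probs))
        assert run_cascade(sched).excess_treatments == expected_excess

    @pytest.mark.parametrize(
        "first, expected_excess", [(0.57, 93), (0.64, 65)]
    )
    def test_all_steps_boosted_scenarios(self, first, expected_excess):
        sched = build_schedule(ScheduleKind.GEOMETRIC_DECLINE, first, 0.10, max_steps=100)
        assert run_cascade(sched).excess_treatments == expected_excess

    def test_continuous_total_matches_geometric_series(self, constant42):
        res = run_cascade(
            constant42, CascadeConfig(rounding=Rounding.CONTINUOUS)
        )
        expected = 100 * (1 - 0.58**9) / 0.42
        assert res.total_treatments == pytest.approx(expected, abs=1e-9)

    def test_exhausted_schedule_raises_with_achieved_coverage(self):
        short = ResponseSchedule(probs=(0.3, 0.3))
        with pytest.raises(NonConvergenceError) as exc:
            run_cascade(short, CascadeConfig())
        assert exc.value.coverage_achieved == pytest.approx(1 - 0.7**2)

    def test_capped_run_flags_nonconvergence_instead_of_raising(self):
        short = ResponseSchedule(probs=(0.3, 0.3))
        res = run_cascade(short, CascadeConfig(allow_nonconverged=True))
        assert not res.converged
        assert res.n_steps == 2

    def test_lower_coverage_targets_shorten_the_cascade(self, declining):
        n_steps = [
            run_cascade(declining, CascadeConfig(coverage_target=c)).n_steps
            for c in (0.70, 0.80, 0.99)
        ]
        assert n_steps == sorted(n_steps)
        assert n_steps[-1] == 14

    @given(sched=schedules_strategy)
    @settings(max_examples=100)
    def test_ledger_conserves_cohort_and_survival_decreases(self, sched):
        res = run_cascade(
            sched,
            CascadeConfig(rounding=Rounding.CONTINUOUS, allow_nonconverged=True),
        )
        survival = 1.0
        for rec in res.steps:
            assert rec.survival_before == pytest.approx(survival)
            # responders-to-date + survivors = cohort, exactly (continuous ledger)
            assert rec.cumulative_response_pct / 100 + rec.survival_after == pytest.approx(1.0)
            assert rec.survival_after < rec.survival_before
            survival = rec.survival_after

    @given(sched=schedules_strategy, data=st.data())
    @settings(max_examples=100)
    def test_raising_any_single_step_never_increases_total(self, sched, data):
        idx = data.draw(st.integers(0, len(sched) - 1))
        bump = data.draw(st.floats(0.0, 1.0))
        probs = list(sched.probs)
        probs[idx] = probs[idx] + (0.99 - probs[idx]) * bump
        cfg = CascadeConfig(rounding=Rounding.CONTINUOUS, allow_nonconverged=True)
        base = run_cascade(sched, cfg)
        raised = run_cascade(sched.with_probs(probs), cfg)
        assert raised.total_treatments <= base.total_treatments + 1e-9

    def test_half_up_and_continuous_totals_differ_by_at_most_half_step(self, declining):
        half_up = run_cascade(declining, CascadeConfig())
        cont = run_cascade(declining, CascadeConfig(rounding=Rounding.CONTINUOUS))
        assert abs(half_up.total_treatments - cont.total_treatments) <= half_up.n_steps / 2


class TestMarkovExpectedTreatments:
    def test_constant_half_response_long_horizon_gives_two(self):
        sched = build_schedule(ScheduleKind.CONSTANT, 0.5, max_steps=200)
        assert markov_expected_treatments(sched, 200) == pytest.approx(2.0, abs=1e-6)

    def test_constant_42_horizon_9_matches_geometric_series(self, constant42):
        expected = (1 - 0.58**9) / 0.42
        assert markov_expected_treatments(constant42, 9) == pytest.approx(expected, abs=1e-10)

    def test_declining_horizon_14_matches_survival_sum(self, declining):
        # brute-force oracle: direct summation of survival products
        s, total = 1.0, 0.0
        for p in declining.probs[:14]:
            total += s
            s *= 1 - p
        assert markov_expected_treatments(declining, 14) == pytest.approx(total, abs=1e-10)
        assert total == pytest.approx(2.3013, abs=5e-5)

    @given(sched=schedules_strategy)
    @settings(max_examples=100)
    def test_fundamental_matrix_equals_survival_sum(self, sched):
        horizon = len(sched)
        s, sum_surv = 1.0, 0.0
        for p in sched.probs:
            sum_surv += s
            s *= 1 - p
        assert markov_expected_treatments(sched, horizon) == pytest.approx(sum_surv, abs=1e-10)

    @given(sched=schedules_strategy)
    @settings(max_examples=50)
    def test_markov_expectation_matches_continuous_cascade_total(self, sched):
        res = run_cascade(
            sched, CascadeConfig(rounding=Rounding.CONTINUOUS, allow_nonconverged=True)
        )
        expected = markov_expected_treatments(sched, res.n_steps) * 100
        assert res.total_treatments == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("p", [0.25, 0.42, 0.5, 0.8])
    def test_infinite_horizon_limit_is_reciprocal_response_rate(self, p):
        sched = build_schedule(ScheduleKind.CONSTANT, p, max_steps=200)
        assert markov_expected_treatments(sched, 200) == pytest.approx(1 / p, abs=1e-6)

    def test_invalid_horizons_rejected(self, declining):
        with pytest.raises(ValueError):
            markov_expected_treatments(declining, 0)
        with pytest.raises(ValueError):
            markov_expected_treatments(declining, len(declining) + 1)


class TestCompareScenarios:
    @pytest.mark.parametrize(
        "alt_excess, expected_pct", [(110, 15), (93, 28), (65, 50), (121, 7), (130, 0)]
    )
    def test_percent_reduction_in_excess_treatments(self, declining, alt_excess, expected_pct):
        base = run_cascade(declining, CascadeConfig())
        assert base.excess_treatments == 130
        # synthesize the alternative by direct construction of the comparison
        from treatcascade import ScenarioComparison

        cmp = ScenarioComparison(baseline_excess=130, alternative_excess=alt_excess)
        assert cmp.pct_reduction == expected_pct
        assert cmp.absolute_reduction == 130 - alt_excess

    def test_full_pipeline_first_step_boost_is_15pct_reduction(self, declining):
        base = run_cascade(declining, CascadeConfig())
        alt = run_cascade(declining.with_probs((0.57,) + declining.probs[1:]))
        cmp = compare_scenarios(base, alt)
        assert (cmp.baseline_excess, cmp.alternative_excess, cmp.pct_reduction) == (130, 110, 15)

    def test_mismatched_configs_rejected(self, declining):
        a = run_cascade(declining, CascadeConfig(cohort_size=100))
        b = run_cascade(declining, CascadeConfig(cohort_size=200))
        with pytest.raises(ValueError):
            compare_scenarios(a, b)

    def test_nonconverged_results_rejected(self, declining):
        short = ResponseSchedule(probs=(0.3,))
        bad = run_cascade(short, CascadeConfig(allow_nonconverged=True))
        good = run_cascade(declining, CascadeConfig())
        with pytest.raises(ValueError):
            compare_scenarios(good, bad)


class TestCumulativeResponseCurve:
    def test_starts_at_zero_and_exceeds_coverage_target(self, declining):
        res = run_cascade(declining, CascadeConfig())
        curve = cumulative_response_curve(res)
        assert curve[0] == (0, 0.0)
        assert curve[-1][1] > 99.0
        values = [v for _, v in curve]
        assert values == sorted(values)

    def test_third_step_values_match_hand_computation(self, declining, constant42):
        dec = cumulative_response_curve(run_cascade(declining))[3][1]
        assert dec == pytest.approx(100 * (1 - 0.5 * 0.55 * 0.595), abs=1e-9)
        assert round(dec) == 84
        const = cumulative_response_curve(run_cascade(constant42))[3][1]
        assert const == pytest.approx(100 * (1 - 0.58**3), abs=1e-9)
        assert round(const) == 80


class TestExports:
    def test_per_step_csv_and_json_summary(self, declining, tmp_path):
        res = run_cascade(declining, CascadeConfig())
        csv_path = tmp_path / "ledger.csv"
        json_path = tmp_path / "summary.json"
        res.to_csv(csv_path)
        res.to_json(json_path)
        import json

        import pandas as pd

        frame = pd.read_csv(csv_path)
        assert list(frame.columns) == [
            "step",
            "response_prob",
            "survival_before",
            "treated",
            "cumulative_response_pct",
        ]
        assert len(frame) == 14
        assert frame["treated"].sum() == 230
        summary = json.loads(json_path.read_text())
        assert summary["n_steps"] == 14
        assert summary["excess_treatments"] == 130
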