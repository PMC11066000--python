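"""Exclusion workflow, mortality accounting, KM/log-rank, decline, ANOVA."""

import numpy as np
import pytest

import robscore as rs
from robscore.exceptions import ValidationError
from robscore.survival import (
    AnimalRecord,
    CohortLedger,
    Event,
    logrank_from_durations,
    mortality_table,
    oneway_anova,
)


def _animal(i, severity=None, events=(), reason=None, group="sah"):
    return AnimalRecord(f"X{i:02d}", group=group, severity=severity,
                        events=list(events), exclusion_reason=reason)


class TestExclusionWorkflow:
    def test_no_exclusions_passes_everyone(self):
        ledger = CohortLedger([_animal(i, "mild", [Event(7, "scheduled_autopsy")]) for i in range(5)])
        valid, scored, report = rs.build_valid_cohort(ledger)
        assert len(valid) == len(scored) == 5
        assert report.entries == []

    def test_all_excluded_empties_both_cohorts(self):
        ledger = CohortLedger(
            [_animal(0, reason="tumor"), _animal(1, reason="intraop_death"),
             _animal(2, reason="missing_day1_data")]
        )
        valid, scored, report = rs.build_valid_cohort(ledger)
        assert (len(valid), len(scored)) == (1, 0)
        assert len(report.entries) == 3

    def test_early_death_inferred_as_unscorable(self):
        ledger = CohortLedger([_animal(0, events=[Event(1, "death")]), _animal(1, "mild", [Event(7, "scheduled_autopsy")])])
        _, scored, report = rs.build_valid_cohort(ledger)
        assert scored.ids() == ["X01"]
        assert report.entries == [("X00", "scoring", "died_before_first_score")]

    def test_contradictory_events_rejected(self):
        with pytest.raises(ValidationError, match="terminal"):
            rs.build_valid_cohort(
                CohortLedger([_animal(0, events=[Event(2, "death"), Event(3, "scheduled_autopsy")])])
            )
        with pytest.raises(ValidationError, match="after terminal"):
            rs.build_valid_cohort(
                CohortLedger([_animal(0, events=[Event(2, "death"), Event(3, "exclusion")])])
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            rs.build_valid_cohort(CohortLedger([_animal(0), _animal(0)]))


class TestMortality:
    def test_no_events_is_zero(self):
        cohort = CohortLedger([_animal(i, "mild") for i in range(4)])
        assert rs.cumulative_mortality(cohort, 5).percent == 0.0

    def test_non_decreasing_in_day(self, scored_cohort):
        values = [rs.cumulative_mortality(scored_cohort, d).percent for d in range(1, 8)]
        assert values == sorted(values)

    def test_same_day_autopsy_still_at_risk(self):
        # One death day 3 plus one autopsy day 3: denominator unchanged on day 3,
        # reduced from day 4 on.
        cohort = CohortLedger(
            [_animal(0, "mild", [Event(3, "death")]),
             _animal(1, "mild", [Event(3, "scheduled_autopsy")]),
             _animal(2, "mild", [Event(7, "scheduled_autopsy")])]
        )
        assert rs.cumulative_mortality(cohort, 3).at_risk == 3
        assert rs.cumulative_mortality(cohort, 4).at_risk == 2

    def test_day_validation(self, scored_cohort):
        with pytest.raises(ValidationError):
            rs.cumulative_mortality(scored_cohort, 0)

    def test_table_contains_overall_and_classes(self, scored_cohort):
        table = mortality_table(scored_cohort, range(1, 8))
        assert set(table["group"]) == {"overall", "severe", "moderate", "mild"}
        d3 = table[(table["day"] == 3) & (table["group"] == "overall")]
        assert d3["mortality_percent"].item() == 13.79


class TestKaplanMeier:
    def test_only_censoring_gives_flat_curve(self):
        cohort = CohortLedger([_animal(i, "mild", [Event(7, "scheduled_autopsy")]) for i in range(5)])
        curve = rs.km_curves(cohort)["mild"]
        assert np.all(curve.survival == 1.0)

    def test_all_die_day_one_drops_to_zero(self):
        cohort = CohortLedger([_animal(i, "severe", [Event(1, "death")]) for i in range(4)])
        curve = rs.km_curves(cohort)["severe"]
        assert curve.survival[-1] == 0.0 and curve.times[-1] == 1.0

    def test_reference_severe_arm_reaches_zero_by_day_four(self, scored_cohort):
        curve = rs.km_curves(scored_cohort)["severe"]
        assert curve.times[-1] == 4.0 and curve.survival[-1] == 0.0

    def test_no_censoring_matches_empirical_survival(self, rng):
        days = rng.integers(1, 6, size=12)
        cohort = CohortLedger(
            [_animal(i, "moderate", [Event(int(d), "death")]) for i, d in enumerate(days)]
        )
        curve = rs.km_curves(cohort)["moderate"]
        for t, s in zip(curve.times, curve.survival):
            if t > 0:
                assert s == pytest.approx(np.mean(days > t))

    def test_empty_class_warns_and_is_omitted(self):
        cohort = CohortLedger([_animal(0, "mild", [Event(7, "scheduled_autopsy")])])
        with pytest.warns(UserWarning, match="severe"):
            curves = rs.km_curves(cohort)
        assert set(curves) == {"mild"}


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        dur = [1, 2, 3, 4, 1, 2, 3, 4]
        grp = ["a"] * 4 + ["b"] * 4
        res = logrank_from_durations(dur, grp, [1] * 8)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_relabeling_invariance(self, rng):
        dur = rng.integers(1, 8, size=20)
        evt = rng.integers(0, 2, size=20)
        grp = np.array(["a"] * 10 + ["b"] * 10)
        swapped = np.where(grp == "a", "z", "y")
        a = logrank_from_durations(dur, grp, evt)
        b = logrank_from_durations(dur, swapped, evt)
        assert a.statistic == pytest.approx(b.statistic)

    def test_censoring_before_first_event_leaves_statistic_unchanged(self):
        # Animals censored before any event are never at risk at an event
        # time, so they cannot influence the statistic.
        dur = [3, 4, 5, 3, 4, 6]
        evt = [1, 1, 0, 1, 1, 0]
        grp = ["a", "a", "a", "b", "b", "b"]
        base = logrank_from_durations(dur, grp, evt)
        extended = logrank_from_durations(dur + [1, 1], grp + ["a", "b"], evt + [0, 0])
        assert extended.statistic == pytest.approx(base.statistic)

    def test_requires_two_groups(self):
        cohort = CohortLedger([_animal(0, "mild", [Event(7, "scheduled_autopsy")])])
        with pytest.raises(ValidationError):
            rs.logrank_test(cohort)

    def test_reference_cohort_is_significant(self, scored_cohort):
        res = rs.logrank_test(scored_cohort)
        assert res.df == 2
        assert res.p_value < 0.05


class TestFirstDecline:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ({1: 10, 2: 10, 3: 10, 4: 8}, 4),
            ({1: 7, 2: 9, 3: 11}, None),
            ({1: 9, 2: 8, 3: 8}, 2),
        ],
    )
    def test_examples(self, scores, expected):
        assert rs.first_decline_day(scores) == expected

    def test_needs_two_days(self):
        with pytest.raises(ValidationError):
            rs.first_decline_day({1: 10})

    def test_reference_survivor_trends(self):
        days = [rs.first_decline_day(s) for s in rs.reference_decline_trends()]
        assert sorted(days) == [4, 4, 4, 4, 5, 5]


class TestAnova:
    def test_constant_groups_report_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = oneway_anova({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        from scipy import stats

        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        res = oneway_anova({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    @pytest.mark.parametrize("adjust", ["tukey", "bonferroni", "holm"])
    def test_pairwise_comparisons_cover_all_pairs(self, rng, adjust):
        groups = {k: rng.normal(m, 1, 8) for k, m in [("a", 0), ("b", 1), ("c", 2)]}
        res = oneway_anova(groups, adjust=adjust)
        assert {frozenset((p.group_a, p.group_b)) for p in res.pairwise} == {
            frozenset(x) for x in [("a", "b"), ("a", "c"), ("b", "c")]
        }
        assert all(0 <= p.p_adj <= 1 for p in res.pairwise)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            oneway_anova({"a": [1.0]})
        with pytest.raises(ValidationError):
            oneway_anova({"a": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            oneway_anova({"a": [1.0, 2.0], "b": [1.0, 2.0]}, adjust="fdr")


class TestSurvivorSummary:
    def test_day_one_everyone_alive(self, scored_cohort):
        summary = rs.survivor_summary(scored_cohort, 1)
        assert summary.total == 29

    def test_empty_cohort(self):
        summary = rs.survivor_summary(CohortLedger([]), 3)
        assert summary.total == 0 and all(v == 0 for v in summary.by_severity.values())

    def test_conservation_every_day(self, scored_cohort):
        # survivors + cumulative deaths + prior scheduled removals = cohort size
        for day in range(1, 8):
            alive = rs.survivor_summary(scored_cohort, day).total
            deaths = sum(
                1 for a in scored_cohort
                if a.mortality_day is not None and a.mortality_day <= day
            )
            removed = sum(
                1 for a in scored_cohort if a.censor_day is not None and a.censor_day < day
            )
            assert alive + deaths + removed == len(scored_cohort)
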