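"""Bundled reference data: a reconstructed event ledger for the ROB
validation cohort.

The original 40-mouse validation experiment reported its exclusion
workflow, per-day mortality and survivor composition only at cohort
level. :func:`reference_cohort` rebuilds a per-animal event ledger that
reproduces every reported count simultaneously:

* 40 enrolled; 1 neck tumour, 1 intra-operative death, 2 suboptimal
  filament insertions -> 36 valid;
* 4 dead/euthanised within 24 h and 3 with missing day-1 data -> 29
  scored (6 severe, 18 moderate, 5 mild by day-1 ROB);
* mortality: 3 severe on day 2, 1 severe on day 3, 2 severe plus 2
  moderate (one death, one humane endpoint) on day 4;
* 8 scheduled autopsies on day 3 and all 13 day-7 survivors harvested
  on day 7.

The severity composition of the day-3 autopsy draw was not reported;
the assignment used here (5 moderate, 3 mild, 0 severe) is the unique
composition consistent with all reported denominators (moderate 2/13
day-7 mortality, 2 mild and 11 moderate survivors, severe 6/6 by day 4).
It is a reconstruction, not observed data, as are the specific kinds
(death vs. humane endpoint) of the severe-group mortality events.
"""

from __future__ import annotations

from .survival import AnimalRecord, CohortLedger, Event, ScoreSeries

__all__ = ["reference_cohort", "reference_decline_trends"]


def reference_cohort() -> CohortLedger:
    """The reconstructed 40-animal event ledger (see module docstring)."""
    animals: list[AnimalRecord] = []

    def add(i: int, **kw) -> None:
        animals.append(AnimalRecord(animal_id=f"A{i:02d}", group="sah", **kw))

    # Validity exclusions (unrelated to SAH severity).
    add(1, exclusion_reason="tumor", events=[Event(0, "exclusion")])
    add(2, exclusion_reason="intraop_death", events=[Event(0, "exclusion")])
    for i in (3, 4):
        add(i, exclusion_reason="filament_suboptimal", events=[Event(0, "exclusion")])
    # Valid but unscored: dead within 24 h, or day-1 data missing.
    for i in range(5, 9):
        add(i, exclusion_reason="died_before_first_score", events=[Event(1, "death")])
    for i in range(9, 12):
        add(i, exclusion_reason="missing_day1_data", events=[Event(1, "exclusion")])
    # Severe (n=6): 3 mortality events day 2, 1 day 3, 2 day 4.
    severe = {12: (2, "death"), 13: (2, "humane_endpoint"), 14: (2, "death"),
              15: (3, "death"), 16: (4, "death"), 17: (4, "humane_endpoint")}
    for i, (day, kind) in severe.items():
        add(i, severity="severe", events=[Event(day, kind)])
    # Moderate (n=18): 5 autopsied day 3, one death and one humane endpoint
    # day 4, 11 survivors harvested day 7.
    for i in range(18, 23):
        add(i, severity="moderate", events=[Event(3, "scheduled_autopsy")])
    add(23, severity="moderate", events=[Event(4, "death")])
    add(24, severity="moderate", events=[Event(4, "humane_endpoint")])
    for i in range(25, 36):
        add(i, severity="moderate", events=[Event(7, "scheduled_autopsy")])
    # Mild (n=5): 3 autopsied day 3, 2 survivors harvested day 7.
    for i in range(36, 39):
        add(i, severity="mild", events=[Event(3, "scheduled_autopsy")])
    for i in range(39, 41):
        add(i, severity="mild", events=[Event(7, "scheduled_autopsy")])

    ledger = CohortLedger(animals)
    ledger.validate()
    return ledger


def reference_decline_trends() -> list[ScoreSeries]:
    """Daily ROB trajectories for six day-7 survivors.

    The reported pattern is that four of six retrospectively examined
    survivors first declined on post-operative day 4 and the other two on
    day 5. The day-by-day totals below are synthetic illustrations of
    that pattern (per-animal trajectories were never published); only the
    first-decline days are meaningful.
    """
    return [
        ScoreSeries("S1", {1: 9, 2: 9, 3: 9, 4: 7, 5: 7, 6: 6, 7: 6}),
        ScoreSeries("S2", {1: 8, 2: 8, 3: 8, 4: 7, 5: 6, 6: 6, 7: 6}),
        ScoreSeries("S3", {1: 10, 2: 10, 3: 10, 4: 8, 5: 8, 6: 7, 7: 7}),
        ScoreSeries("S4", {1: 9, 2: 10, 3: 10, 4: 9, 5: 8, 6: 8, 7: 8}),
        ScoreSeries("S5", {1: 11, 2: 11, 3: 11, 4: 11, 5: 9, 6: 9, 7: 8}),
        ScoreSeries("S6", {1: 12, 2: 12, 3: 12, 4: 12, 5: 10, 6: 10, 7: 9}),
    ]
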