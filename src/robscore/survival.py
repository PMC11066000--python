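"""Cohort ledger construction, mortality accounting and group statistics.

Implements the analysis conventions of the ROB validation protocol:

* Exclusion workflow. Animals excluded for reasons unrelated to SAH
  severity (neck tumour, intra-operative death, suboptimal filament
  insertion) are dropped from the *valid* cohort; animals that died or
  were euthanised before the first assessment, or whose day-1 data are
  missing, remain valid but cannot be graded and are dropped from the
  *scored* cohort.
* Mortality. Humane-endpoint euthanasia counts as a mortality event
  alongside spontaneous death; scheduled autopsy euthanasia is planned
  tissue harvest and is right-censoring. The at-risk denominator for
  cumulative mortality at day *d* excludes scheduled removals occurring
  strictly before *d*, so same-day autopsies still count as at risk.
* Kaplan-Meier / log-rank. Standard product-limit estimates per severity
  class (via :mod:`lifelines`), with the k-group log-rank test
  (df = k - 1) and its asymptotic chi-square p-value. Deaths recorded
  "on day d" occur at time d exactly; ties use the standard log-rank
  tie correction.
* One-way ANOVA with configurable pairwise multiple-comparison
  adjustment (Tukey HSD by default; Bonferroni or Holm on pooled
  t-tests otherwise).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .scoring import SEVERITY_LEVELS

__all__ = [
    "MORTALITY_KINDS",
    "CENSORING_KINDS",
    "VALIDITY_EXCLUSIONS",
    "SCORING_EXCLUSIONS",
    "Event",
    "AnimalRecord",
    "CohortLedger",
    "ScoreSeries",
    "ExclusionReport",
    "MortalityPoint",
    "KMCurve",
    "LogrankResult",
    "AnovaResult",
    "PairwiseComparison",
    "SurvivorSummary",
    "build_valid_cohort",
    "cumulative_mortality",
    "subgroup_mortality",
    "mortality_table",
    "km_curves",
    "logrank_test",
    "logrank_from_durations",
    "first_decline_day",
    "oneway_anova",
    "survivor_summary",
]

#: Event kinds that count toward mortality.
MORTALITY_KINDS = frozenset({"death", "humane_endpoint"})
#: Event kinds treated as right-censoring.
CENSORING_KINDS = frozenset({"scheduled_autopsy"})
TERMINAL_KINDS = MORTALITY_KINDS | CENSORING_KINDS
EVENT_KINDS = TERMINAL_KINDS | {"exclusion"}

#: Exclusion reasons that remove an animal from the valid cohort.
VALIDITY_EXCLUSIONS = ("tumor", "intraop_death", "filament_suboptimal")
#: Exclusion reasons that keep an animal valid but unscored.
SCORING_EXCLUSIONS = ("died_before_first_score", "missing_day1_data")


@dataclass(frozen=True)
class Event:
    """One dated event in an animal's history (day 0 = surgery day)."""

    day: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}; expected one of {sorted(EVENT_KINDS)}")
        if not (isinstance(self.day, (int, np.integer)) and self.day >= 0):
            raise ValidationError(f"event day must be an integer >= 0, got {self.day!r}")
        object.__setattr__(self, "day", int(self.day))


@dataclass
class AnimalRecord:
    """One animal's identity, group, severity and event history."""

    animal_id: str
    group: str = "sah"
    severity: Optional[str] = None
    events: list[Event] = field(default_factory=list)
    exclusion_reason: Optional[str] = None

    def validate(self) -> None:
        if self.severity is not None and self.severity not in SEVERITY_LEVELS:
            raise ValidationError(
                f"animal {self.animal_id}: severity {self.severity!r} not in {SEVERITY_LEVELS}"
            )
        terminals = [e for e in self.events if e.kind in TERMINAL_KINDS]
        if len(terminals) > 1:
            raise ValidationError(
                f"animal {self.animal_id}: more than one terminal event ({terminals})"
            )
        if terminals:
            t = terminals[0]
            late = [e for e in self.events if e.day > t.day]
            if late:
                raise ValidationError(
                    f"animal {self.animal_id}: event {late[0]} recorded after terminal "
                    f"{t.kind} on day {t.day}"
                )

    @property
    def terminal_event(self) -> Optional[Event]:
        for e in self.events:
            if e.kind in TERMINAL_KINDS:
                return e
        return None

    @property
    def mortality_day(self) -> Optional[int]:
        t = self.terminal_event
        return t.day if t is not None and t.kind in MORTALITY_KINDS else None

    @property
    def censor_day(self) -> Optional[int]:
        t = self.terminal_event
        return t.day if t is not None and t.kind in CENSORING_KINDS else None


@dataclass
class CohortLedger:
    """An ordered collection of animal records."""

    animals: list[AnimalRecord]

    @property
    def enrolled_n(self) -> int:
        return len(self.animals)

    def __len__(self) -> int:
        return len(self.animals)

    def __iter__(self):
        return iter(self.animals)

    def ids(self) -> list[str]:
        return [a.animal_id for a in self.animals]

    def validate(self) -> None:
        seen = set()
        for a in self.animals:
            if a.animal_id in seen:
                raise ValidationError(f"duplicate animal id {a.animal_id!r}")
            seen.add(a.animal_id)
            a.validate()

    def subset(self, group: str | None = None, severity: str | None = None) -> "CohortLedger":
        sel = [
            a
            for a in self.animals
            if (group is None or a.group == group)
            and (severity is None or a.severity == severity)
        ]
        return CohortLedger(sel)


@dataclass(frozen=True)
class ScoreSeries:
    """Daily ROB totals for one animal, keyed by post-operative day."""

    animal_id: str
    scores: Mapping[int, int]

    def __post_init__(self) -> None:
        days = list(self.scores)
        if any(not (isinstance(d, (int, np.integer)) and d >= 1) for d in days):
            raise ValidationError(f"{self.animal_id}: days must be integers >= 1")
        object.__setattr__(
            self, "scores", dict(sorted((int(d), int(s)) for d, s in self.scores.items()))
        )


@dataclass
class ExclusionReport:
    """Which animals each exclusion rule removed, plus peri-operative mortality.

    Peri-operative mortality counts intra-operative deaths plus mortality
    within the first 24 h, over the animals actually subjected to the
    induction attempt (enrolled minus exclusions unrelated to the
    procedure outcome, i.e. tumour and suboptimal filament).
    """

    enrolled_n: int
    valid_n: int
    scored_n: int
    entries: list[tuple[str, str, str]]  # (animal_id, stage, reason)
    perioperative_deaths: int
    perioperative_denominator: int

    @property
    def perioperative_mortality_percent(self) -> float:
        if self.perioperative_denominator == 0:
            return 0.0
        return 100.0 * self.perioperative_deaths / self.perioperative_denominator

    def to_dict(self) -> dict:
        return {
            "enrolled_n": self.enrolled_n,
            "valid_n": self.valid_n,
            "scored_n": self.scored_n,
            "excluded": [
                {"animal_id": a, "stage": s, "reason": r} for a, s, r in self.entries
            ],
            "perioperative_deaths": self.perioperative_deaths,
            "perioperative_denominator": self.perioperative_denominator,
            "perioperative_mortality_percent": round(self.perioperative_mortality_percent, 2),
        }


def build_valid_cohort(
    ledger: CohortLedger,
) -> tuple[CohortLedger, CohortLedger, ExclusionReport]:
    """Apply the exclusion workflow: enrolled -> valid -> scored.

    Returns ``(valid, scored, report)``. Animals whose ``exclusion_reason``
    is a validity exclusion leave the valid cohort; animals with a scoring
    exclusion, or with a mortality event on day <= 1 (they could not
    receive a day-1 score), leave the scored cohort.
    """
    ledger.validate()
    valid_animals: list[AnimalRecord] = []
    scored_animals: list[AnimalRecord] = []
    entries: list[tuple[str, str, str]] = []
    for a in ledger:
        if a.exclusion_reason in VALIDITY_EXCLUSIONS:
            entries.append((a.animal_id, "validity", a.exclusion_reason))
            continue
        valid_animals.append(a)
        if a.exclusion_reason in SCORING_EXCLUSIONS:
            entries.append((a.animal_id, "scoring", a.exclusion_reason))
        elif a.mortality_day is not None and a.mortality_day <= 1:
            entries.append((a.animal_id, "scoring", "died_before_first_score"))
        elif a.exclusion_reason is not None:
            raise ValidationError(
                f"animal {a.animal_id}: unknown exclusion reason {a.exclusion_reason!r}"
            )
        else:
            scored_animals.append(a)

    peri_deaths = sum(
        1
        for a in ledger
        if a.exclusion_reason == "intraop_death"
        or (a.exclusion_reason not in VALIDITY_EXCLUSIONS and a.mortality_day is not None and a.mortality_day <= 1)
    )
    peri_denom = ledger.enrolled_n - sum(
        1 for a in ledger if a.exclusion_reason in ("tumor", "filament_suboptimal")
    )
    report = ExclusionReport(
        enrolled_n=ledger.enrolled_n,
        valid_n=len(valid_animals),
        scored_n=len(scored_animals),
        entries=entries,
        perioperative_deaths=peri_deaths,
        perioperative_denominator=peri_denom,
    )
    return CohortLedger(valid_animals), CohortLedger(scored_animals), report


@dataclass(frozen=True)
class MortalityPoint:
    """Cumulative mortality at one day: counts and percent."""

    day: int
    deaths: int
    at_risk: int
    percent: float

    @property
    def display(self) -> float:
        """Percent rounded to two decimals for tabulation."""
        return round(self.percent, 2)


def cumulative_mortality(cohort: CohortLedger, day: int) -> MortalityPoint:
    """Cumulative mortality through ``day`` with autopsy-adjusted denominator.

    Numerator: deaths plus humane-endpoint euthanasias on days <= ``day``.
    Denominator: cohort size minus scheduled-autopsy removals occurring
    strictly before ``day`` (animals harvested on ``day`` itself were
    still at risk that day).
    """
    if not (isinstance(day, (int, np.integer)) and day >= 1):
        raise ValidationError(f"day must be an integer >= 1, got {day!r}")
    deaths = sum(1 for a in cohort if a.mortality_day is not None and a.mortality_day <= day)
    removed = sum(1 for a in cohort if a.censor_day is not None and a.censor_day < day)
    at_risk = len(cohort) - removed
    percent = 100.0 * deaths / at_risk if at_risk > 0 else 0.0
    return MortalityPoint(int(day), deaths, at_risk, percent)


def subgroup_mortality(cohort: CohortLedger, severity: str, day: int) -> MortalityPoint:
    """Cumulative mortality restricted to one severity class."""
    if severity not in SEVERITY_LEVELS:
        raise ValidationError(f"severity {severity!r} not in {SEVERITY_LEVELS}")
    return cumulative_mortality(cohort.subset(severity=severity), day)


def mortality_table(cohort: CohortLedger, days: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-day mortality for the overall cohort and each severity class."""
    if days is None:
        horizon = max((e.day for a in cohort for e in a.events), default=1)
        days = range(1, max(horizon, 1) + 1)
    rows = []
    labels = ["overall"] + [s for s in SEVERITY_LEVELS if len(cohort.subset(severity=s))]
    for day in days:
        for label in labels:
            sub = cohort if label == "overall" else cohort.subset(severity=label)
            p = cumulative_mortality(sub, int(day))
            rows.append(
                {
                    "day": p.day,
                    "group": label,
                    "deaths": p.deaths,
                    "at_risk": p.at_risk,
                    "mortality_percent": p.display,
                }
            )
    return pd.DataFrame(rows)


def _durations(animals: Sequence[AnimalRecord], horizon: int | None) -> tuple[np.ndarray, np.ndarray]:
    durations, observed = [], []
    default_horizon = horizon
    if default_horizon is None:
        terminal_days = [a.terminal_event.day for a in animals if a.terminal_event]
        default_horizon = max(terminal_days, default=None)
    for a in animals:
        t = a.terminal_event
        if t is not None:
            durations.append(t.day)
            observed.append(1 if t.kind in MORTALITY_KINDS else 0)
        else:
            if default_horizon is None:
                raise ValidationError(
                    f"animal {a.animal_id} has no terminal event and no horizon was given"
                )
            warnings.warn(
                f"animal {a.animal_id} has no terminal event; censored at day {default_horizon}",
                stacklevel=3,
            )
            durations.append(default_horizon)
            observed.append(0)
    return np.asarray(durations, dtype=float), np.asarray(observed, dtype=int)


@dataclass(frozen=True)
class KMCurve:
    """One Kaplan-Meier step function with its at-risk table."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int


def km_curves(cohort: CohortLedger, horizon: int | None = None) -> dict[str, KMCurve]:
    """Kaplan-Meier survival per severity class.

    Mortality events are events; scheduled autopsies are right-censored at
    their day. Severity classes with no animals are omitted with a
    warning, as are animals with no severity assigned.
    """
    curves: dict[str, KMCurve] = {}
    unassigned = [a for a in cohort if a.severity is None]
    if unassigned:
        warnings.warn(
            f"{len(unassigned)} animals have no severity assigned and are omitted from KM curves"
        )
    for label in SEVERITY_LEVELS:
        sub = cohort.subset(severity=label)
        if len(sub) == 0:
            warnings.warn(f"severity class {label!r} has no animals; omitted")
            continue
        durations, observed = _durations(sub.animals, horizon)
        kmf = KaplanMeierFitter()
        kmf.fit(durations, observed, label=label)
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        curves[label] = KMCurve(
            label=label,
            times=timeline,
            survival=kmf.survival_function_[label].to_numpy(dtype=float),
            at_risk=kmf.event_table["at_risk"].to_numpy(dtype=int),
            n=len(sub),
            n_events=int(observed.sum()),
        )
    return curves


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_from_durations(durations, groups, observed) -> LogrankResult:
    """k-group log-rank test on raw duration/event arrays.

    The p-value comes from the chi-square asymptotic distribution with
    df = k - 1.
    """
    durations = np.asarray(durations, dtype=float)
    groups = np.asarray(groups)
    observed = np.asarray(observed, dtype=int)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(durations, groups, observed)
    return LogrankResult(
        statistic=float(res.test_statistic), df=len(labels) - 1, p_value=float(res.p_value)
    )


def logrank_test(cohort: CohortLedger, horizon: int | None = None) -> LogrankResult:
    """Log-rank comparison of survival across severity classes."""
    animals = [a for a in cohort if a.severity is not None]
    if not animals:
        raise ValidationError("no animals with an assigned severity class")
    durations, observed = _durations(animals, horizon)
    groups = np.array([a.severity for a in animals])
    return logrank_from_durations(durations, groups, observed)


def first_decline_day(series: ScoreSeries | Mapping[int, int]) -> Optional[int]:
    """Smallest day whose ROB total is below the previous scored day's.

    Returns ``None`` for a non-decreasing series. Days need not be
    consecutive; comparison is against the previous *scored* day.
    """
    scores = series.scores if isinstance(series, ScoreSeries) else dict(series)
    days = sorted(scores)
    if len(days) < 2:
        raise ValidationError("decline detection needs at least two scored days")
    for prev, cur in zip(days, days[1:]):
        if scores[cur] < scores[prev]:
            return cur
    return None


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    diff: float
    p_adj: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    adjust: str
    pairwise: tuple[PairwiseComparison, ...]


def oneway_anova(groups: Mapping[str, Sequence[float]], adjust: str = "tukey") -> AnovaResult:
    """One-way ANOVA across named groups with adjusted pairwise comparisons.

    ``adjust`` is ``"tukey"`` (Tukey HSD), ``"bonferroni"`` or ``"holm"``
    (pooled two-sample t-tests with family-wise correction). With zero
    variance everywhere the F statistic is undefined; this is reported as
    F = 0, p = 1 with a warning.
    """
    if adjust not in ("tukey", "bonferroni", "holm"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.ndim != 1 or len(v) < 2:
            raise ValidationError(f"group {k!r} needs at least two values")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"group {k!r} contains non-finite values")

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0.0:
        warnings.warn("all observations identical: ANOVA F is undefined, reporting p = 1")
        pairs = tuple(
            PairwiseComparison(a, b, 0.0, 1.0) for a, b in itertools.combinations(labels, 2)
        )
        return AnovaResult(0.0, 1.0, adjust, pairs)

    f_stat, p_value = stats.f_oneway(*arrays.values())

    if adjust == "tukey":
        values = pooled
        group_col = np.concatenate([[k] * len(arrays[k]) for k in labels])
        res = pairwise_tukeyhsd(values, group_col)
        unique = list(res.groupsunique)
        i_idx, j_idx = np.triu_indices(len(unique), 1)
        pairs = tuple(
            PairwiseComparison(str(unique[i]), str(unique[j]), float(md), float(p))
            for i, j, md, p in zip(i_idx, j_idx, res.meandiffs, res.pvalues)
        )
    else:
        raw, combos, diffs = [], [], []
        for a, b in itertools.combinations(labels, 2):
            t_res = stats.ttest_ind(arrays[a], arrays[b], equal_var=True)
            raw.append(t_res.pvalue)
            combos.append((a, b))
            diffs.append(float(arrays[b].mean() - arrays[a].mean()))
        adj = multipletests(raw, method=adjust)[1]
        pairs = tuple(
            PairwiseComparison(a, b, d, float(p))
            for (a, b), d, p in zip(combos, diffs, adj)
        )
    return AnovaResult(float(f_stat), float(p_value), adjust, pairs)


@dataclass(frozen=True)
class SurvivorSummary:
    """Animals alive at a day, partitioned by severity class."""

    day: int
    total: int
    by_severity: Mapping[str, int]


def survivor_summary(cohort: CohortLedger, day: int) -> SurvivorSummary:
    """Count animals alive at ``day`` per severity class.

    Alive means: no mortality event on or before ``day`` and no scheduled
    removal strictly before ``day`` (animals harvested on ``day`` itself
    were alive that day). Survivors + cumulative deaths + prior removals
    always equal the cohort size.
    """
    if not (isinstance(day, (int, np.integer)) and day >= 1):
        raise ValidationError(f"day must be an integer >= 1, got {day!r}")
    alive = [
        a
        for a in cohort
        if not (a.mortality_day is not None and a.mortality_day <= day)
        and not (a.censor_day is not None and a.censor_day < day)
    ]
    by_sev = {s: sum(1 for a in alive if a.severity == s) for s in SEVERITY_LEVELS}
    return SurvivorSummary(int(day), len(alive), by_sev)
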