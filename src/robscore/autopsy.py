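"""Sugawara-style autopsy grading and ROB/autopsy concordance.

The basal cistern is divided into six segments; each segment is graded
0-3 by the amount of subarachnoid blood clot (0: no blood, 1: minimal
blood, 2: moderate clot with recognizable arteries, 3: clot obliterating
all arteries). The segment sum (0-18) maps onto the same three severity
labels the ROB score uses, via configurable cut-points. The packaged
defaults (mild 0-7, moderate 8-12, severe 13-18) follow the common
tertile-style reading of the Sugawara total used in perforation-model
work; labs applying different cut-points can pass their own
:class:`AutopsyCutpoints`.

Note the orientation difference: a *higher* autopsy total means *more*
blood and a worse outcome, while a higher ROB total means a better one.
Concordance compares the mapped severity labels, not the totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .exceptions import ValidationError
from .scoring import SEVERITY_LEVELS

__all__ = [
    "N_SEGMENTS",
    "AutopsyCutpoints",
    "AutopsyGrade",
    "ConcordanceResult",
    "autopsy_total",
    "concordance",
]

#: Number of basal-cistern segments graded.
N_SEGMENTS = 6

#: Rank order used by the within-one-level concordance tolerance.
_SEVERITY_RANK = {"mild": 0, "moderate": 1, "severe": 2}


@dataclass(frozen=True)
class AutopsyCutpoints:
    """Closed integer ranges of the 0-18 total per severity label."""

    bands: tuple[tuple[str, int, int], ...] = (
        ("mild", 0, 7),
        ("moderate", 8, 12),
        ("severe", 13, 18),
    )

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b[1])
        if ordered[0][1] != 0 or ordered[-1][2] != 18:
            raise ValidationError("autopsy cut-points must span totals 0..18")
        for (_, _, hi), (_, lo, _) in zip(ordered, ordered[1:]):
            if lo != hi + 1:
                raise ValidationError("autopsy cut-points must partition 0..18")
        if {label for label, _, _ in self.bands} != set(SEVERITY_LEVELS):
            raise ValidationError(f"autopsy labels must be {SEVERITY_LEVELS}")

    def severity(self, total: int) -> str:
        for label, lo, hi in self.bands:
            if lo <= total <= hi:
                return label
        raise ValidationError(f"total {total} outside 0..18")


@dataclass(frozen=True)
class AutopsyGrade:
    """Six segment grades, their total and the mapped severity label."""

    segment_grades: tuple[int, ...]
    total: int
    severity: str


def autopsy_total(segment_grades, cutpoints: AutopsyCutpoints | None = None) -> AutopsyGrade:
    """Sum six 0-3 segment grades and map the total to a severity label."""
    cutpoints = cutpoints or AutopsyCutpoints()
    grades = tuple(segment_grades)
    if len(grades) != N_SEGMENTS:
        raise ValidationError(f"exactly {N_SEGMENTS} segment grades are required, got {len(grades)}")
    clean = []
    for g in grades:
        if not (float(g).is_integer() and 0 <= int(g) <= 3):
            raise ValidationError(f"segment grade must be an integer in 0..3, got {g!r}")
        clean.append(int(g))
    total = sum(clean)
    return AutopsyGrade(tuple(clean), total, cutpoints.severity(total))


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between ROB and autopsy severity labels over shared animals."""

    n_compared: int
    n_agreeing: int
    pairs: tuple[tuple[str, str, str, bool], ...]  # (animal_id, rob, autopsy, agree)

    @property
    def agreement_fraction(self) -> float:
        if self.n_compared == 0:
            return 0.0
        return self.n_agreeing / self.n_compared

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_agreeing": self.n_agreeing,
            "agreement_fraction": self.agreement_fraction,
            "pairs": [
                {"animal_id": a, "rob_severity": r, "autopsy_severity": s, "agree": bool(g)}
                for a, r, s, g in self.pairs
            ],
        }


def concordance(
    rob_classes: Mapping[str, str],
    autopsy_classes: Mapping[str, str],
    *,
    within_one_level: bool = False,
) -> ConcordanceResult:
    """Severity-label agreement between the two grading systems.

    Both inputs map animal id -> severity label and must cover the same
    animals. Agreement is exact label equality by default; with
    ``within_one_level=True`` adjacent labels (mild/moderate,
    moderate/severe) also count as agreeing.
    """
    missing_rob = sorted(set(autopsy_classes) - set(rob_classes))
    missing_aut = sorted(set(rob_classes) - set(autopsy_classes))
    if missing_rob or missing_aut:
        raise ValidationError(
            "animal ids do not match: "
            f"missing from ROB input {missing_rob}, missing from autopsy input {missing_aut}"
        )
    pairs = []
    for animal_id in rob_classes:
        r, s = rob_classes[animal_id], autopsy_classes[animal_id]
        for label in (r, s):
            if label not in _SEVERITY_RANK:
                raise ValidationError(f"unknown severity label {label!r} for {animal_id}")
        agree = (
            abs(_SEVERITY_RANK[r] - _SEVERITY_RANK[s]) <= 1 if within_one_level else r == s
        )
        pairs.append((animal_id, r, s, agree))
    n_agree = sum(1 for *_, g in pairs if g)
    return ConcordanceResult(len(pairs), n_agree, tuple(pairs))
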