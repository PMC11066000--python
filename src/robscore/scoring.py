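"""ROB composite severity scoring.

The ROB score grades post-SAH status in the circle-of-Willis perforation
mouse model from three objective daily measurements: Rotarod latency to
fall (seconds, 300-s endpoint), open-field path distance over a
key-sampled video window (tracker pixel units), and body-weight loss
relative to the pre-operative weight (percent). Each measurement maps to
a 1-5 sub-score and the composite total (3-15) classifies the animal as
severe (3-6), moderate (7-10) or mild (11-15).

Band edges are configuration, not code: the defaults ship in
``criteria.yaml`` next to this module and can be replaced wholesale via
:meth:`ScoringCriteria.from_yaml`, so labs can recalibrate cut-offs
without touching the scoring logic. Where a printed criteria table leaves
touching bin edges ambiguous, the defaults resolve the tie
lower-inclusive unless a strict inequality is explicit (the open-field
top band is strictly ``> 1000``; the weight-loss end bands are strictly
``< 5`` and ``> 20``); the 300-s Rotarod cap is the only latency scoring
the top motor sub-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .exceptions import ValidationError

__all__ = [
    "ROTAROD_ENDPOINT_S",
    "SEVERITY_LEVELS",
    "Band",
    "SeverityBand",
    "ScoringCriteria",
    "RobComponents",
    "RobScore",
    "score_rotarod",
    "score_openfield",
    "score_bwl",
    "severity_for_total",
    "compute_rob",
]

#: Latency cap of the accelerating-rod protocol, in seconds.
ROTAROD_ENDPOINT_S = 300.0

#: Severity classes, ordered from worst to best outcome.
SEVERITY_LEVELS = ("severe", "moderate", "mild")


@dataclass(frozen=True)
class Band:
    """One sub-score band: an interval of raw values mapping to a score.

    ``lo_open``/``hi_open`` mark exclusive edges; both edges are inclusive
    by default. A zero-width closed band (e.g. exactly 300 s) is valid.
    """

    score: int
    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False

    def contains(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        return above and below

    @classmethod
    def from_dict(cls, d: dict) -> "Band":
        return cls(
            score=int(d["score"]),
            lo=float(d["min"]),
            hi=float(d["max"]),
            lo_open=bool(d.get("min_open", False)),
            hi_open=bool(d.get("max_open", False)),
        )

    def to_dict(self) -> dict:
        out = {"score": self.score, "min": self.lo, "max": self.hi}
        if self.lo_open:
            out["min_open"] = True
        if self.hi_open:
            out["max_open"] = True
        return out


@dataclass(frozen=True)
class SeverityBand:
    """A closed integer range of composite totals mapping to a class label."""

    label: str
    lo: int
    hi: int

    def contains(self, total: int) -> bool:
        return self.lo <= total <= self.hi

    @classmethod
    def from_dict(cls, d: dict) -> "SeverityBand":
        return cls(label=str(d["label"]), lo=int(d["min"]), hi=int(d["max"]))

    def to_dict(self) -> dict:
        return {"label": self.label, "min": self.lo, "max": self.hi}


def _check_contiguous(bands: tuple[Band, ...], lo: float, hi: float, name: str) -> None:
    """Bands must partition [lo, hi] (hi may be +inf) with no gap or overlap."""
    ordered = sorted(bands, key=lambda b: (b.lo, b.hi))
    first, last = ordered[0], ordered[-1]
    if not first.contains(lo) and not (math.isinf(lo) and first.lo == lo):
        raise ValidationError(f"{name} bands do not cover the domain start {lo}")
    for a, b in zip(ordered, ordered[1:]):
        if a.hi != b.lo or a.hi_open == b.lo_open:
            raise ValidationError(
                f"{name} bands {a.score} and {b.score} do not tile: "
                f"edge {a.hi}/{b.lo} is covered {'twice' if not a.hi_open and not b.lo_open else 'never' if a.hi_open and b.lo_open else 'inconsistently'}"
            )
    if math.isinf(hi):
        if not math.isinf(last.hi):
            raise ValidationError(f"{name} bands do not extend to +inf")
    elif not last.contains(hi):
        raise ValidationError(f"{name} bands do not cover the domain end {hi}")


@dataclass(frozen=True)
class ScoringCriteria:
    """The full ROB criteria: three sub-score band sets plus severity bands.

    Validated on construction: each component's bands must tile its domain
    exactly once (rotarod [0, 300], open-field [0, inf), weight loss
    (-inf, inf)), use scores {1..5}, and the severity bands must partition
    the total range 3..15.
    """

    rotarod: tuple[Band, ...]
    openfield: tuple[Band, ...]
    bwl: tuple[Band, ...]
    severity: tuple[SeverityBand, ...]

    def __post_init__(self) -> None:
        for name, bands, lo, hi in (
            ("rotarod", self.rotarod, 0.0, ROTAROD_ENDPOINT_S),
            ("openfield", self.openfield, 0.0, math.inf),
            ("bwl", self.bwl, -math.inf, math.inf),
        ):
            if sorted(b.score for b in bands) != [1, 2, 3, 4, 5]:
                raise ValidationError(f"{name} bands must carry scores 1..5 exactly once")
            _check_contiguous(bands, lo, hi, name)
        ordered = sorted(self.severity, key=lambda b: b.lo)
        if ordered[0].lo != 3 or ordered[-1].hi != 15:
            raise ValidationError("severity bands must span totals 3..15")
        for a, b in zip(ordered, ordered[1:]):
            if b.lo != a.hi + 1:
                raise ValidationError(
                    f"severity bands '{a.label}' and '{b.label}' do not partition 3..15"
                )
        if {b.label for b in self.severity} != set(SEVERITY_LEVELS):
            raise ValidationError(f"severity labels must be {SEVERITY_LEVELS}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringCriteria":
        return cls(
            rotarod=tuple(Band.from_dict(b) for b in d["rotarod"]),
            openfield=tuple(Band.from_dict(b) for b in d["openfield"]),
            bwl=tuple(Band.from_dict(b) for b in d["bwl"]),
            severity=tuple(SeverityBand.from_dict(b) for b in d["severity"]),
        )

    def to_dict(self) -> dict:
        return {
            "rotarod": [b.to_dict() for b in self.rotarod],
            "openfield": [b.to_dict() for b in self.openfield],
            "bwl": [b.to_dict() for b in self.bwl],
            "severity": [b.to_dict() for b in self.severity],
        }

    @classmethod
    def from_yaml(cls, path) -> "ScoringCriteria":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def default(cls) -> "ScoringCriteria":
        return _default_criteria()


@lru_cache(maxsize=1)
def _default_criteria() -> ScoringCriteria:
    text = resources.files(__package__).joinpath("criteria.yaml").read_text("utf-8")
    return ScoringCriteria.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class RobComponents:
    """Raw component measurements for one animal-day.

    rotarod_seconds
        Mean latency to fall over the three trials, 0-300 s (clamping to
        the 300-s endpoint happens upstream; out-of-range values are
        rejected here).
    openfield_distance
        Key-frame path distance in tracker pixel units, >= 0.
    bwl_percent
        Body-weight loss percent; negative when the animal gained weight.
    """

    rotarod_seconds: float
    openfield_distance: float
    bwl_percent: float

    def __post_init__(self) -> None:
        _validate_rotarod(self.rotarod_seconds)
        _validate_openfield(self.openfield_distance)
        _validate_bwl(self.bwl_percent)


@dataclass(frozen=True)
class RobScore:
    """The three 1-5 sub-scores, their total (3-15) and severity class."""

    r_score: int
    o_score: int
    b_score: int
    total: int
    severity: str

    @classmethod
    def from_subscores(
        cls, r_score: int, o_score: int, b_score: int, criteria: ScoringCriteria | None = None
    ) -> "RobScore":
        """Assemble a score from pre-binned sub-scores (traceability override).

        Normal operation recomputes sub-scores from raw measurements; this
        constructor exists for ledgers that only retain binned values.
        """
        for name, s in (("r_score", r_score), ("o_score", o_score), ("b_score", b_score)):
            if not (isinstance(s, (int,)) and 1 <= s <= 5):
                raise ValidationError(f"{name} must be an integer in 1..5, got {s!r}")
        total = r_score + o_score + b_score
        return cls(r_score, o_score, b_score, total, severity_for_total(total, criteria))


def _validate_rotarod(seconds: float) -> None:
    if not math.isfinite(seconds) or seconds < 0 or seconds > ROTAROD_ENDPOINT_S:
        raise ValidationError(
            f"rotarod latency must lie in [0, {ROTAROD_ENDPOINT_S:g}] s, got {seconds!r}"
        )


def _validate_openfield(distance: float) -> None:
    if not math.isfinite(distance) or distance < 0:
        raise ValidationError(
            f"open-field distance must be a finite value >= 0, got {distance!r}"
        )


def _validate_bwl(percent: float) -> None:
    if not math.isfinite(percent):
        raise ValidationError(f"body-weight loss must be finite, got {percent!r}")


def _lookup(bands: tuple[Band, ...], x: float, component: str) -> int:
    for band in bands:
        if band.contains(x):
            return band.score
    raise ValidationError(f"{component} value {x!r} matches no configured band")


def score_rotarod(seconds: float, criteria: ScoringCriteria | None = None) -> int:
    """Map a mean Rotarod latency (s) to its 1-5 sub-score."""
    criteria = criteria or ScoringCriteria.default()
    _validate_rotarod(seconds)
    return _lookup(criteria.rotarod, float(seconds), "rotarod")


def score_openfield(distance: float, criteria: ScoringCriteria | None = None) -> int:
    """Map an open-field path distance (tracker units) to its 1-5 sub-score."""
    criteria = criteria or ScoringCriteria.default()
    _validate_openfield(distance)
    return _lookup(criteria.openfield, float(distance), "openfield")


def score_bwl(bwl_percent: float, criteria: ScoringCriteria | None = None) -> int:
    """Map a body-weight-loss percent to its 1-5 sub-score.

    Weight gain (negative percent) falls in the healthiest band and
    scores 5.
    """
    criteria = criteria or ScoringCriteria.default()
    _validate_bwl(bwl_percent)
    return _lookup(criteria.bwl, float(bwl_percent), "bwl")


def severity_for_total(total: int, criteria: ScoringCriteria | None = None) -> str:
    """Severity class for a composite total in 3..15."""
    criteria = criteria or ScoringCriteria.default()
    if not (isinstance(total, int) and 3 <= total <= 15):
        raise ValidationError(f"ROB total must be an integer in 3..15, got {total!r}")
    for band in criteria.severity:
        if band.contains(total):
            return band.label
    raise ValidationError(f"total {total} matches no severity band")  # pragma: no cover


def compute_rob(components: RobComponents, criteria: ScoringCriteria | None = None) -> RobScore:
    """Score one animal-day: three sub-scores, total and severity class."""
    criteria = criteria or ScoringCriteria.default()
    r = score_rotarod(components.rotarod_seconds, criteria)
    o = score_openfield(components.openfield_distance, criteria)
    b = score_bwl(components.bwl_percent, criteria)
    total = r + o + b
    return RobScore(r, o, b, total, severity_for_total(total, criteria))
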