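"""Synthetic cohort generation for end-to-end protocol testing.

The simulator emulates the statistical shape of the validation cohort so
that every pipeline stage (behavioural measurement, scoring, survival
analysis, autopsy concordance) can be exercised without animal data:

* Day-1 Rotarod latency, open-field distance and body-weight loss are
  drawn per latent severity class from truncated normals whose location,
  scale and truncation range default to the class-wise summary statistics
  of the validation cohort (truncation shifts the realised moments; see
  :meth:`TruncNorm.mean`).
* Subsequent days fluctuate around the day-1 value until a per-animal
  decline day (drawn from {4, 5}), after which performance degrades
  linearly and weight loss grows.
* Death is sampled daily from class- and day-specific hazards whose
  defaults reproduce the reported mortality pattern (severe: 1/2 on day
  2, 1/3 on day 3, certain death on day 4; moderate: ~2/13 on day 4;
  mild: none). A configurable fraction of mortality events is recorded
  as humane-endpoint euthanasia rather than found death.
* Scheduled autopsies are drawn uniformly among animals alive at the
  planned day (default: 8 on day 3); every animal still alive at the
  horizon (day 7) is harvested then. Autopsy segment grades are drawn
  from class-specific grade distributions.
* Open-field distances can optionally be realised as random-walk tracks
  whose key-frame path length equals the drawn distance exactly, so the
  behavioural pipeline is exercised end to end.

Everything derives from one seeded :class:`numpy.random.Generator`
stream, so a cohort is fully reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import DEFAULT_FPS, KEYFRAME_WINDOW, TrackedPath, path_distance, sample_keyframes
from .exceptions import ValidationError
from .scoring import RobComponents, ScoringCriteria, compute_rob
from .survival import AnimalRecord, CohortLedger, Event

__all__ = [
    "TruncNorm",
    "ClassDay1",
    "DeclineModel",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "make_track_fixture",
    "render_track_frames",
]


@dataclass(frozen=True)
class TruncNorm:
    """A normal(loc, scale) truncated to [lo, hi].

    ``loc``/``scale`` are the latent normal's parameters; the realised
    mean and SD of the truncated distribution differ whenever the
    truncation is asymmetric (use :meth:`mean`/:meth:`std` for those).
    """

    loc: float
    scale: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValidationError(f"scale must be >= 0, got {self.scale}")
        if not (self.lo <= self.loc <= self.hi):
            raise ValidationError(
                f"range [{self.lo}, {self.hi}] must contain the location {self.loc}"
            )

    def _ab(self) -> tuple[float, float]:
        if self.scale == 0:
            raise ValidationError("degenerate distribution (scale 0) has no shape parameters")
        a = (self.lo - self.loc) / self.scale
        b = (self.hi - self.loc) / self.scale
        if stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-12:
            raise ValidationError(
                f"truncation [{self.lo}, {self.hi}] leaves no probability mass "
                f"for normal({self.loc}, {self.scale})"
            )
        return a, b

    def sample(self, rng: np.random.Generator, size=None):
        if self.scale == 0:
            return np.full(size, self.loc) if size is not None else self.loc
        a, b = self._ab()
        return stats.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale, size=size, random_state=rng)

    def mean(self) -> float:
        """Theoretical mean of the truncated distribution."""
        if self.scale == 0:
            return self.loc
        a, b = self._ab()
        return float(stats.truncnorm.mean(a, b, loc=self.loc, scale=self.scale))

    def std(self) -> float:
        """Theoretical SD of the truncated distribution."""
        if self.scale == 0:
            return 0.0
        a, b = self._ab()
        return float(stats.truncnorm.std(a, b, loc=self.loc, scale=self.scale))

    def to_dict(self) -> dict:
        return {"loc": self.loc, "scale": self.scale, "lo": self.lo, "hi": self.hi}


@dataclass(frozen=True)
class ClassDay1:
    """Day-1 measurement distributions for one severity class."""

    rotarod: TruncNorm
    openfield: TruncNorm
    bwl: TruncNorm

    def to_dict(self) -> dict:
        return {
            "rotarod": self.rotarod.to_dict(),
            "openfield": self.openfield.to_dict(),
            "bwl": self.bwl.to_dict(),
        }


def _default_day1() -> dict[str, ClassDay1]:
    """Class-wise day-1 distributions matching the validation cohort summaries."""
    return {
        "severe": ClassDay1(
            rotarod=TruncNorm(38.0, 60.0, 0.0, 154.0),
            openfield=TruncNorm(130.0, 92.0, 39.0, 277.0),
            bwl=TruncNorm(11.00, 5.36, 3.21, 16.23),
        ),
        "moderate": ClassDay1(
            rotarod=TruncNorm(106.0, 51.0, 0.0, 177.0),
            openfield=TruncNorm(425.0, 251.0, 90.0, 944.0),
            bwl=TruncNorm(9.07, 3.87, 2.73, 14.89),
        ),
        "mild": ClassDay1(
            rotarod=TruncNorm(188.0, 30.0, 151.0, 215.0),
            openfield=TruncNorm(643.0, 169.0, 492.0, 891.0),
            bwl=TruncNorm(2.23, 1.00, 1.57, 4.00),
        ),
        "sham": ClassDay1(
            rotarod=TruncNorm(289.0, 12.0, 276.0, 300.0),
            openfield=TruncNorm(1156.0, 163.0, 982.0, 1305.0),
            bwl=TruncNorm(1.87, 0.59, 1.24, 2.40),
        ),
    }


def _default_hazards() -> dict[str, dict[int, float]]:
    """Daily death hazards reproducing the reported mortality pattern.

    Severe: cumulative 1/2 by day 2, 2/3 by day 3, 1 by day 4.
    Moderate: a single at-risk fraction of ~2/13 concentrated on day 4.
    Mild: no mortality.
    """
    return {
        "severe": {2: 0.5, 3: 1.0 / 3.0, 4: 1.0},
        "moderate": {4: 2.0 / 13.0},
        "mild": {},
    }


@dataclass(frozen=True)
class DeclineModel:
    """Post-day-1 trajectory parameters.

    Before the decline day, measurements fluctuate multiplicatively
    around the day-1 value with SD ``daily_noise``. From the decline day
    on, Rotarod and open-field values shrink by ``rotarod_frac`` /
    ``openfield_frac`` of the day-1 value per day, and weight loss grows
    by ``bwl_step`` percentage points per day.
    """

    rotarod_frac: float = 0.2
    openfield_frac: float = 0.2
    bwl_step: float = 2.0
    daily_noise: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that defines a synthetic cohort, including its seed."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"severe": 6, "moderate": 18, "mild": 5}
    )
    n_sham: int = 3
    day1: Mapping[str, ClassDay1] = field(default_factory=_default_day1)
    hazards: Mapping[str, Mapping[int, float]] = field(default_factory=_default_hazards)
    decline_day_probs: Mapping[int, float] = field(
        default_factory=lambda: {4: 2.0 / 3.0, 5: 1.0 / 3.0}
    )
    decline: DeclineModel = field(default_factory=DeclineModel)
    autopsy_plan: tuple[tuple[int, int], ...] = ((3, 8),)
    horizon: int = 7
    humane_fraction: float = 0.25
    weight_range_g: tuple[float, float] = (25.3, 35.5)
    make_tracks: bool = False
    track_frames: int = KEYFRAME_WINDOW + 1
    fps: float = DEFAULT_FPS
    #: "rob": ledger severity is the day-1 ROB assignment (protocol-faithful,
    #: includes misclassification); "truth": ledger severity is the latent
    #: class driving the hazard, giving groups of exactly the configured sizes.
    severity_from: str = "rob"
    seed: int = 0

    def validate(self) -> None:
        if self.severity_from not in ("rob", "truth"):
            raise ValidationError(f"severity_from must be 'rob' or 'truth', got {self.severity_from!r}")
        for cls, n in self.n_per_class.items():
            if cls not in self.day1:
                raise ValidationError(f"no day-1 distributions for class {cls!r}")
            if n < 0:
                raise ValidationError(f"n_per_class[{cls!r}] must be >= 0")
        for cls, hz in self.hazards.items():
            for day, h in hz.items():
                if not (0.0 <= h <= 1.0):
                    raise ValidationError(f"hazard {h} for {cls!r} day {day} outside [0, 1]")
        total_p = sum(self.decline_day_probs.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValidationError(f"decline-day probabilities sum to {total_p}, not 1")
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1")
        if not (0.0 <= self.humane_fraction <= 1.0):
            raise ValidationError("humane_fraction must lie in [0, 1]")
        if self.track_frames < KEYFRAME_WINDOW + 1:
            raise ValidationError(
                f"track_frames must be >= {KEYFRAME_WINDOW + 1} to cover the key-frame window"
            )

    def to_dict(self) -> dict:
        return {
            "n_per_class": dict(self.n_per_class),
            "n_sham": self.n_sham,
            "day1": {k: v.to_dict() for k, v in self.day1.items()},
            "hazards": {k: {int(d): float(h) for d, h in v.items()} for k, v in self.hazards.items()},
            "decline_day_probs": {int(k): float(v) for k, v in self.decline_day_probs.items()},
            "decline": asdict(self.decline),
            "autopsy_plan": [list(x) for x in self.autopsy_plan],
            "horizon": self.horizon,
            "humane_fraction": self.humane_fraction,
            "weight_range_g": list(self.weight_range_g),
            "make_tracks": self.make_tracks,
            "track_frames": self.track_frames,
            "fps": self.fps,
            "severity_from": self.severity_from,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kw = dict(d)
        if "day1" in kw:
            kw["day1"] = {
                k: ClassDay1(**{c: TruncNorm(**tv) for c, tv in v.items()})
                for k, v in kw["day1"].items()
            }
        if "hazards" in kw:
            kw["hazards"] = {k: {int(day): float(h) for day, h in v.items()} for k, v in kw["hazards"].items()}
        if "decline_day_probs" in kw:
            kw["decline_day_probs"] = {int(k): float(v) for k, v in kw["decline_day_probs"].items()}
        if "decline" in kw:
            kw["decline"] = DeclineModel(**kw["decline"])
        if "autopsy_plan" in kw:
            kw["autopsy_plan"] = tuple(tuple(int(x) for x in item) for item in kw["autopsy_plan"])
        if "weight_range_g" in kw:
            kw["weight_range_g"] = tuple(kw["weight_range_g"])
        return cls(**kw)


#: Per-class segment-grade distributions over {0, 1, 2, 3} for autopsied brains.
_AUTOPSY_GRADE_P = {
    "severe": (0.02, 0.08, 0.30, 0.60),
    "moderate": (0.10, 0.30, 0.45, 0.15),
    "mild": (0.45, 0.40, 0.13, 0.02),
    "sham": (0.95, 0.05, 0.0, 0.0),
}


@dataclass
class SimulatedCohort:
    """Outputs of one simulated cohort run."""

    config: SimulationConfig
    ledger: CohortLedger
    assessments: pd.DataFrame
    tracks: Optional[pd.DataFrame]
    autopsy: pd.DataFrame
    truth: pd.DataFrame


def draw_day1(dists: ClassDay1, rng: np.random.Generator) -> tuple[float, float, float]:
    """One animal's day-1 (rotarod mean, open-field distance, weight-loss %)."""
    rt = float(np.clip(dists.rotarod.sample(rng), 0.0, 300.0))
    ot = float(max(dists.openfield.sample(rng), 0.0))
    bwl = float(dists.bwl.sample(rng))
    return rt, ot, bwl


def _trials_from_mean(rt_mean: float, rng: np.random.Generator) -> tuple[float, float, float]:
    """Three trial latencies averaging exactly to ``rt_mean`` within [0, 300]."""
    spread = rng.uniform(0.0, min(20.0, rt_mean, 300.0 - rt_mean))
    return (rt_mean - spread, rt_mean, rt_mean + spread)


def simulate_cohort(config: SimulationConfig | None = None, rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort (see module docstring).

    Severity recorded in the ledger is the day-1 ROB assignment computed
    from the simulated measurements (as in the real protocol); the latent
    class each animal was drawn from — which drives its death hazard —
    is reported separately in the ``truth`` table.
    """
    config = config or SimulationConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    criteria = ScoringCriteria.default()

    class _State:
        __slots__ = (
            "animal_id", "group", "true_class", "rt1", "ot1", "bwl1", "pre_weight",
            "decline_day", "severity", "rob_severity", "alive", "removed", "events",
        )

    states: list[_State] = []
    counter = 0
    decline_days = sorted(config.decline_day_probs)
    decline_p = [config.decline_day_probs[d] for d in decline_days]

    members = [(cls, config.n_per_class.get(cls, 0)) for cls in ("severe", "moderate", "mild")]
    members.append(("sham", config.n_sham))
    assessment_rows: list[dict] = []
    for cls, n in members:
        for _ in range(n):
            counter += 1
            s = _State()
            s.animal_id = f"M{counter:03d}"
            s.group = "sham" if cls == "sham" else "sah"
            s.true_class = cls
            s.rt1, s.ot1, s.bwl1 = draw_day1(config.day1[cls], rng)
            s.pre_weight = float(rng.uniform(*config.weight_range_g))
            s.decline_day = int(rng.choice(decline_days, p=decline_p))
            s.alive = True
            s.removed = False
            s.events = []
            rob = compute_rob(RobComponents(s.rt1, s.ot1, s.bwl1), criteria)
            s.rob_severity = None if s.group == "sham" else rob.severity
            if s.group == "sham":
                s.severity = None
            else:
                s.severity = rob.severity if config.severity_from == "rob" else cls
            states.append(s)
            assessment_rows.append(_assessment_row(s, 1, s.rt1, s.ot1, s.bwl1, rng))

    # Sham animals are harvested after the day-1 assessment.
    for s in states:
        if s.group == "sham":
            s.events.append(Event(1, "scheduled_autopsy"))
            s.removed = True

    plan = {day: n for day, n in config.autopsy_plan}
    decline = config.decline
    for day in range(2, config.horizon + 1):
        for s in states:
            if not s.alive or s.removed:
                continue
            hazard = config.hazards.get(s.true_class, {}).get(day, 0.0)
            if rng.random() < hazard:
                kind = "humane_endpoint" if rng.random() < config.humane_fraction else "death"
                s.events.append(Event(day, kind))
                s.alive = False
                continue
            if day < s.decline_day:
                rt = s.rt1 * (1.0 + rng.normal(0.0, decline.daily_noise))
                ot = s.ot1 * (1.0 + rng.normal(0.0, decline.daily_noise))
                bwl = s.bwl1 + rng.normal(0.0, decline.daily_noise * 10.0)
            else:
                k = day - s.decline_day + 1
                rt = s.rt1 * max(1.0 - decline.rotarod_frac * k, 0.0) * (1.0 + rng.normal(0.0, decline.daily_noise))
                ot = s.ot1 * max(1.0 - decline.openfield_frac * k, 0.0) * (1.0 + rng.normal(0.0, decline.daily_noise))
                bwl = s.bwl1 + decline.bwl_step * k + rng.normal(0.0, decline.daily_noise * 10.0)
            rt = float(np.clip(rt, 0.0, 300.0))
            ot = float(max(ot, 0.0))
            bwl = float(min(bwl, 99.0))
            assessment_rows.append(_assessment_row(s, day, rt, ot, bwl, rng))
        if day in plan:
            eligible = [s for s in states if s.alive and not s.removed]
            n_pick = min(plan[day], len(eligible))
            picks = rng.choice(len(eligible), size=n_pick, replace=False) if n_pick else []
            for idx in sorted(int(i) for i in np.atleast_1d(picks)):
                eligible[idx].events.append(Event(day, "scheduled_autopsy"))
                eligible[idx].removed = True
    for s in states:
        if s.alive and not s.removed:
            s.events.append(Event(config.horizon, "scheduled_autopsy"))
            s.removed = True

    autopsy_rows = []
    for s in states:
        harvest = next((e for e in s.events if e.kind == "scheduled_autopsy"), None)
        if harvest is None:
            continue
        grades = rng.choice(4, size=6, p=_AUTOPSY_GRADE_P[s.true_class])
        row = {"animal_id": s.animal_id, "day": harvest.day}
        row.update({f"seg{i + 1}": int(g) for i, g in enumerate(grades)})
        autopsy_rows.append(row)

    assessments = pd.DataFrame(assessment_rows)
    tracks = None
    if config.make_tracks:
        track_rows = []
        for row in assessment_rows:
            track = make_track_fixture(
                row["ot_distance"], n_frames=config.track_frames, fps=config.fps, rng=rng
            )
            frame = pd.DataFrame(
                {
                    "animal_id": row["animal_id"],
                    "day": row["day"],
                    "frame": track.frame_indices,
                    "x": track.positions[:, 0],
                    "y": track.positions[:, 1],
                }
            )
            track_rows.append(frame)
        tracks = pd.concat(track_rows, ignore_index=True)

    ledger = CohortLedger(
        [
            AnimalRecord(
                animal_id=s.animal_id, group=s.group, severity=s.severity, events=list(s.events)
            )
            for s in states
        ]
    )
    ledger.validate()
    truth = pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in states],
            "group": [s.group for s in states],
            "true_class": [s.true_class for s in states],
            "rob_severity": [s.rob_severity for s in states],
            "decline_day": [s.decline_day for s in states],
        }
    )
    return SimulatedCohort(
        config=config,
        ledger=ledger,
        assessments=assessments,
        tracks=tracks,
        autopsy=pd.DataFrame(autopsy_rows),
        truth=truth,
    )


def _assessment_row(s, day: int, rt: float, ot: float, bwl: float, rng) -> dict:
    rt1, rt2, rt3 = _trials_from_mean(rt, rng)
    weight = s.pre_weight * (1.0 - bwl / 100.0)
    return {
        "animal_id": s.animal_id,
        "group": s.group,
        "day": day,
        "rt1": rt1,
        "rt2": rt2,
        "rt3": rt3,
        "ot_distance": ot,
        "preop_weight_g": s.pre_weight,
        "weight_g": weight,
    }


def make_track_fixture(
    target_distance: float,
    n_frames: int = KEYFRAME_WINDOW + 1,
    fps: float = DEFAULT_FPS,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    start: tuple[float, float] = (0.0, 0.0),
    step_sd: float = 2.0,
    window_start: int = 0,
) -> TrackedPath:
    """A random-walk track whose key-frame path length equals ``target_distance``.

    The walk is rescaled about its start so the key-sampled path length
    over the default window (anchored at ``window_start``) matches the
    target to within floating-point rounding; a zero target yields a
    stationary track.
    """
    if target_distance < 0:
        raise ValidationError(f"target distance must be >= 0, got {target_distance}")
    if n_frames < window_start + KEYFRAME_WINDOW + 1:
        raise ValidationError(
            f"n_frames={n_frames} is below the minimum key-frame window "
            f"({window_start + KEYFRAME_WINDOW + 1} frames)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    origin = np.asarray(start, dtype=float)
    if target_distance == 0:
        positions = np.tile(origin, (n_frames, 1))
        return TrackedPath(np.arange(n_frames), positions, fps)
    steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2))
    positions = origin + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    track = TrackedPath(np.arange(n_frames), positions, fps)
    length = path_distance(sample_keyframes(track, window_start))
    scale = target_distance / length
    positions = origin + (positions - origin) * scale
    return TrackedPath(np.arange(n_frames), positions, fps)


def render_track_frames(
    track: TrackedPath,
    *,
    blob_radius: int = 4,
    margin: int = 10,
) -> tuple[TrackedPath, np.ndarray]:
    """Render a track as a grayscale frame stack with a dark marker blob.

    Positions are translated (distances preserved) so the whole path fits
    the canvas; the translated track is returned alongside the (n, H, W)
    float stack (background 1.0, blob 0.0) for marker-tracking tests.
    """
    from skimage.draw import disk

    shift = margin + blob_radius - track.positions.min(axis=0)
    positions = track.positions + shift
    extent = positions.max(axis=0) + margin + blob_radius
    width, height = int(math.ceil(extent[0])), int(math.ceil(extent[1]))
    frames = np.ones((len(track), height, width), dtype=float)
    for i, (x, y) in enumerate(positions):
        rr, cc = disk((y, x), blob_radius, shape=(height, width))
        frames[i, rr, cc] = 0.0
    return TrackedPath(track.frame_indices, positions, track.fps), frames
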