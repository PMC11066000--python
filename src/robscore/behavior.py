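"""Raw behavioural recordings -> ROB component measurements.

Covers the three measurement pipelines feeding the composite score:

* Rotarod: three accelerating-rod trials per animal-day, each clamped to
  the 300-s endpoint, averaged arithmetically.
* Open field: a 30-FPS video of the released animal; the analysis window
  is the 160 frames following the release frame, sampled at five-frame
  intervals (33 key positions), and the scored quantity is the total
  path length of the ear marker over those key positions, in raw tracker
  pixel units (no spatial calibration). Net start-to-end displacement is
  also exposed but is not the scored quantity.
* Body-weight loss: (pre - post) / pre x 100 %, negative on weight gain.

:func:`track_marker` re-implements the dark-marker centroid tracking the
protocol delegates to video-tracking software, so that synthetic frame
stacks can be pushed through the full pipeline in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.util import img_as_float

from .exceptions import MarkerLostError, ValidationError
from .scoring import ROTAROD_ENDPOINT_S

__all__ = [
    "DEFAULT_FPS",
    "KEYFRAME_WINDOW",
    "KEYFRAME_STEP",
    "TrackedPath",
    "mean_rotarod",
    "sample_keyframes",
    "path_distance",
    "net_displacement",
    "track_marker",
    "body_weight_loss",
]

#: Recording frame rate of the open-field video protocol.
DEFAULT_FPS = 30.0
#: Number of frames following the release frame in the analysis window.
KEYFRAME_WINDOW = 160
#: Key frames are taken every this many frames within the window.
KEYFRAME_STEP = 5


@dataclass(frozen=True)
class TrackedPath:
    """Time-ordered 2-D marker positions with their frame indices.

    ``positions`` holds (x, y) coordinates in tracker pixel units, one row
    per entry of the strictly increasing ``frame_indices``.
    """

    frame_indices: np.ndarray
    positions: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_indices, dtype=np.int64)
        pos = np.asarray(self.positions, dtype=float)
        if idx.ndim != 1 or len(idx) < 1:
            raise ValidationError("a track needs at least one frame")
        if pos.shape != (len(idx), 2):
            raise ValidationError(
                f"positions shape {pos.shape} does not match {len(idx)} frame indices"
            )
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValidationError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("positions must be finite")
        object.__setattr__(self, "frame_indices", idx)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.frame_indices)

    @property
    def duration_s(self) -> float:
        """Elapsed time between first and last frame, in seconds."""
        return float(self.frame_indices[-1] - self.frame_indices[0]) / self.fps


def mean_rotarod(latencies) -> float:
    """Arithmetic mean of the three trial latencies, clamped to [0, 300] s.

    Latencies recorded past the 300-s endpoint are clamped to the endpoint
    before averaging, so the result always lies in [0, 300].
    """
    lat = np.asarray(latencies, dtype=float)
    if lat.shape != (3,):
        raise ValidationError(f"exactly three Rotarod trials are required, got {lat.shape}")
    if not np.all(np.isfinite(lat)):
        raise ValidationError(f"Rotarod latencies must be finite, got {latencies!r}")
    return float(np.clip(lat, 0.0, ROTAROD_ENDPOINT_S).mean())


def sample_keyframes(
    track: TrackedPath,
    start_frame: int,
    n_frames: int = KEYFRAME_WINDOW,
    step: int = KEYFRAME_STEP,
) -> TrackedPath:
    """Key positions at ``start_frame, start_frame+step, ...`` through the window.

    The window is inclusive of both endpoints: the defaults (160 frames,
    step 5) yield 33 key positions anchored at the release frame.
    """
    if n_frames < 1 or step < 1:
        raise ValidationError("n_frames and step must be positive")
    wanted = np.arange(start_frame, start_frame + n_frames + 1, step, dtype=np.int64)
    lookup = {int(f): i for i, f in enumerate(track.frame_indices)}
    rows = []
    for f in wanted:
        if int(f) not in lookup:
            raise ValidationError(
                f"frame {int(f)} is missing from the track "
                f"(key-frame window {start_frame}..{start_frame + n_frames})"
            )
        rows.append(lookup[int(f)])
    return TrackedPath(wanted, track.positions[rows], track.fps)


def _positions(track) -> np.ndarray:
    if isinstance(track, TrackedPath):
        return track.positions
    return np.asarray(track, dtype=float)


def path_distance(track) -> float:
    """Total path length: sum of Euclidean distances between consecutive positions.

    Accepts a :class:`TrackedPath` or a plain (n, 2) coordinate array.
    Zero iff every position is identical.
    """
    pos = _positions(track)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 2:
        raise ValidationError(f"path distance needs >= 2 positions of shape (n, 2), got {pos.shape}")
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def net_displacement(track) -> float:
    """Straight-line distance from first to last position (not the scored quantity)."""
    pos = _positions(track)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 2:
        raise ValidationError(f"displacement needs >= 2 positions of shape (n, 2), got {pos.shape}")
    return float(np.linalg.norm(pos[-1] - pos[0]))


def track_marker(
    frames,
    init_position,
    *,
    threshold: float = 0.5,
    search_radius: float = 50.0,
    min_area: int = 1,
    fps: float = DEFAULT_FPS,
) -> TrackedPath:
    """Track a dark marker blob through a grayscale frame stack.

    Each frame is binarised at ``threshold`` (after rescaling to [0, 1]);
    the centroid of the connected dark blob nearest the previous position
    becomes the new position. If no blob of at least ``min_area`` pixels
    lies within ``search_radius`` pixels of the previous position the
    marker is considered lost and :class:`MarkerLostError` reports the
    frame index.

    Parameters mirror what a video-tracking GUI exposes; positions are
    returned as (x, y) = (column, row) pixel coordinates.
    """
    stack = np.asarray(frames)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValidationError(f"frames must be a non-empty (n, H, W) stack, got {stack.shape}")
    stack = img_as_float(stack)
    prev = np.asarray(init_position, dtype=float)
    if prev.shape != (2,):
        raise ValidationError("init_position must be a 2-D point (x, y)")
    out = np.empty((stack.shape[0], 2))
    for i, frame in enumerate(stack):
        labels = measure.label(frame < threshold)
        best, best_d = None, math.inf
        for region in measure.regionprops(labels):
            if region.area < min_area:
                continue
            cy, cx = region.centroid
            d = math.hypot(cx - prev[0], cy - prev[1])
            if d < best_d:
                best, best_d = (cx, cy), d
        if best is None or best_d > search_radius:
            raise MarkerLostError(i)
        prev = np.array(best)
        out[i] = best
    return TrackedPath(np.arange(stack.shape[0]), out, fps)


def body_weight_loss(pre_g: float, post_g: float) -> float:
    """Body-weight loss percent: (pre - post) / pre x 100.

    Negative when the animal gained weight.
    """
    if not (math.isfinite(pre_g) and pre_g > 0):
        raise ValidationError(f"pre-operative weight must be > 0 g, got {pre_g!r}")
    if not (math.isfinite(post_g) and post_g > 0):
        raise ValidationError(f"post-operative weight must be > 0 g, got {post_g!r}")
    return (pre_g - post_g) / pre_g * 100.0
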