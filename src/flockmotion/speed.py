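"""Real-world speed estimation from rectified pixel trajectories.

After the camera view is rectified to a top-down plane (see
:mod:`flockmotion.geometry`), an animal's speed over a frame window
``[N, M]`` is

    V = dY * W / ((M - N) * dt)

where ``dY`` is its displacement in top-down pixels, ``W`` the metres
represented by one top-down pixel, and ``dt = 1/fps`` the frame interval
(55.56 ms at the default 18 FPS).  The faithful default measures vertical
displacement only — the rectification is constructed so that vertical pixel
shift is proportional to distance travelled — while ``mode="euclidean"``
uses the full planar displacement, which is never smaller.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .geometry import Homography, apply_homography
from .tracks_io import TrackSet, Trajectory

__all__ = [
    "SpeedSample",
    "SpeedSeries",
    "SpeedConfig",
    "frame_interval",
    "transform_trackset",
    "compute_speed",
    "compute_speeds",
    "summarize_speeds",
]

logger = logging.getLogger(__name__)


def frame_interval(fps: float) -> float:
    """Seconds elapsed between consecutive frames: 1/fps."""
    if not fps > 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    return 1.0 / fps


@dataclass(frozen=True)
class SpeedSample:
    """Speed of one track over one frame window [N, M]."""

    track_id: int
    window: tuple[int, int]  # (N, M) frame indices, M > N
    delta_y: float  # displacement in top-down pixels
    velocity_v: float  # m/s

    def __post_init__(self) -> None:
        n, m = self.window
        if m <= n:
            raise ValueError(f"window must satisfy M > N, got {self.window}")
        if self.velocity_v < 0:
            raise ValueError(f"speed must be nonnegative, got {self.velocity_v}")


@dataclass
class SpeedSeries:
    """Ordered speed samples of one track with summary statistics (m/s)."""

    track_id: int
    samples: list[SpeedSample] = field(default_factory=list)

    @property
    def velocities(self) -> np.ndarray:
        return np.array([s.velocity_v for s in self.samples])

    @property
    def mean(self) -> float:
        return float(self.velocities.mean())

    @property
    def min(self) -> float:
        return float(self.velocities.min())

    @property
    def max(self) -> float:
        return float(self.velocities.max())

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class SpeedConfig:
    """Parameters of the speed computation.

    window
        Window length M − N in frames; default 18 (one second at 18 FPS).
    mode
        "vertical" uses |v_M − v_N| only (faithful default); "euclidean"
        uses the planar displacement magnitude.
    pixel_scale_w
        Metres per top-down pixel (W).
    """

    fps: float = 18.0
    window: int = 18
    mode: Literal["vertical", "euclidean"] = "vertical"
    pixel_scale_w: float = 1.0

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1 frame, got {self.window}")
        if self.mode not in ("vertical", "euclidean"):
            raise ValueError(f"unknown displacement mode {self.mode!r}")
        if not self.pixel_scale_w > 0:
            raise ValueError(f"pixel_scale_w must be > 0, got {self.pixel_scale_w}")


def transform_trackset(ts: TrackSet, h: Homography) -> TrackSet:
    """Map every centroid of ``ts`` into the top-down plane through ``h``.

    Identities and frame indices are preserved; detections that map to the
    line at infinity are dropped with a warning.
    """
    from .geometry import CalibrationError

    out = TrackSet(fps=ts.fps, frame_size=None)
    dropped = 0
    for tid in sorted(ts.trajectories):
        for det in ts.trajectories[tid]:
            try:
                u, v = apply_homography(h, det.centroid)
            except CalibrationError:
                dropped += 1
                continue
            from dataclasses import replace

            out.add(replace(det, centroid=(float(u), float(v)), bbox=None))
    if dropped:
        logger.warning("transform_trackset: dropped %d detection(s) mapping to infinity", dropped)
    return out


def compute_speed(traj: Trajectory, cfg: SpeedConfig) -> SpeedSeries:
    """Sliding-window speeds of one top-down trajectory.

    One sample is produced per window start N for which both endpoint frames
    N and M = N + window and every frame in between are present; windows
    containing detection gaps are skipped (displacement across a gap is not
    fabricated by interpolation).  A trajectory shorter than window + 1
    detections yields an empty series with a warning.
    """
    series = SpeedSeries(track_id=traj.track_id)
    dets = traj.detections
    if len(dets) < cfg.window + 1:
        warnings.warn(
            f"track {traj.track_id}: {len(dets)} detections < window+1 "
            f"({cfg.window + 1}); no speed samples",
            stacklevel=2,
        )
        return series
    dt = frame_interval(cfg.fps)
    by_frame = {d.frame: d for d in dets}
    first, last = dets[0].frame, dets[-1].frame
    skipped = 0
    for n in range(first, last - cfg.window + 1):
        m = n + cfg.window
        if any(f not in by_frame for f in range(n, m + 1)):
            skipped += 1
            continue
        a, b = np.asarray(by_frame[n].centroid), np.asarray(by_frame[m].centroid)
        if cfg.mode == "vertical":
            disp = abs(b[1] - a[1])
        else:
            disp = float(np.hypot(*(b - a)))
        v = disp * cfg.pixel_scale_w / ((m - n) * dt)
        series.samples.append(
            SpeedSample(track_id=traj.track_id, window=(n, m), delta_y=float(disp), velocity_v=v)
        )
    if skipped:
        logger.info("track %d: skipped %d window(s) containing gaps", traj.track_id, skipped)
    return series


def compute_speeds(ts: TrackSet, cfg: SpeedConfig | None = None,
                   h: Homography | None = None) -> dict[int, SpeedSeries]:
    """Speed series for every track of a TrackSet.

    If a homography is given the set is rectified first and W is taken from
    it; otherwise ``ts`` is assumed to already be in top-down coordinates.
    """
    if cfg is None:
        cfg = SpeedConfig(fps=ts.fps)
    if h is not None:
        ts = transform_trackset(ts, h)
        from dataclasses import replace as _r

        cfg = SpeedConfig(fps=cfg.fps, window=cfg.window, mode=cfg.mode,
                          pixel_scale_w=h.pixel_scale_w)
    return {tid: compute_speed(traj, cfg) for tid, traj in sorted(ts.trajectories.items())}


def summarize_speeds(series: Mapping[int, SpeedSeries] | Iterable[SpeedSeries]) -> dict:
    """Per-track and cohort summary (mean / min / max, m/s).

    The cohort velocity range is [min over tracks, max over tracks]; tracks
    with no samples are reported but excluded from cohort statistics.
    Raises if no track has any sample.
    """
    if isinstance(series, Mapping):
        series = list(series.values())
    else:
        series = list(series)
    per_track = {}
    pooled = []
    for s in series:
        if len(s) == 0:
            per_track[s.track_id] = {"n_samples": 0}
            continue
        per_track[s.track_id] = {
            "n_samples": len(s),
            "mean_mps": s.mean,
            "min_mps": s.min,
            "max_mps": s.max,
        }
        pooled.append(s.velocities)
    if not pooled:
        raise ValueError("no speed samples in any track")
    allv = np.concatenate(pooled)
    return {
        "per_track": per_track,
        "cohort": {
            "n_tracks": len(pooled),
            "n_samples": int(allv.size),
            "mean_mps": float(allv.mean()),
            "velocity_range_mps": [float(allv.min()), float(allv.max())],
        },
    }
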