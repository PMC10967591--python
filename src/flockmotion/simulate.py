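"""Synthetic flock simulator with known ground-truth kinematics.

Generates small flocks (1-20 birds) moving in a rectangular floor arena
under a correlated random walk — persistent heading with wrapped-Gaussian
turning noise, speed following a mean-reverting walk around a configured
mean (default 0.05 m/s) clipped to configured bounds (default 0-0.21 m/s),
reflective walls — then projects the world tracks through a configurable
perspective camera into pixel coordinates and degrades them into realistic
tracker output (centroid jitter, missed detections, false positives,
identity swaps).

Everything downstream — calibration, rectification, the speed equation and
the CLEAR-MOT metrics — can therefore be validated end to end against known
truth without any video data.  Two observation presets emulate an easy and
a hard visual condition: ``"dyed"`` (birds individually colour-marked, low
noise) and ``"undyed"`` (visually similar birds, elevated noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import Homography, apply_homography, fit_homography
from .tracks_io import Detection, MaskRLE, TrackSet, encode_rle

__all__ = [
    "SimConfigError",
    "ObservationModel",
    "SimConfig",
    "GroundTruthSet",
    "simulate_flock",
    "project_to_pixels",
    "degrade",
    "render_masks",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ObservationModel:
    """Tracker failure modes applied to perfect pixel tracks.

    centroid_jitter_sigma
        Isotropic Gaussian localization noise, px.
    miss_prob
        Probability each detection is dropped.
    false_positive_rate
        Poisson mean of spurious detections per frame, uniform over the
        frame, each with a fresh identity.
    id_swap_prob
        Per-frame probability that the two currently nearest birds have
        their identities transposed from that frame onward (the persistent
        label error a real tracker commits during an occlusion).
    """

    centroid_jitter_sigma: float = 0.0
    miss_prob: float = 0.0
    false_positive_rate: float = 0.0
    id_swap_prob: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 0 <= self.miss_prob <= 1 or not 0 <= self.id_swap_prob <= 1:
            raise SimConfigError("probabilities must lie in [0, 1]")
        if self.centroid_jitter_sigma < 0 or self.false_positive_rate < 0:
            raise SimConfigError("sigma and false-positive rate must be >= 0")

    @classmethod
    def preset(cls, name: str) -> "ObservationModel":
        """Named presets: "dyed" (low noise), "undyed" (elevated noise), "noiseless"."""
        presets = {
            "noiseless": cls(name="noiseless"),
            "dyed": cls(centroid_jitter_sigma=1.0, miss_prob=0.02,
                        false_positive_rate=0.01, id_swap_prob=0.001, name="dyed"),
            "undyed": cls(centroid_jitter_sigma=2.0, miss_prob=0.05,
                          false_positive_rate=0.05, id_swap_prob=0.005, name="undyed"),
        }
        try:
            return presets[name]
        except KeyError:
            raise SimConfigError(f"unknown observation preset {name!r}; "
                                 f"choose from {sorted(presets)}") from None


# Default camera: the arena rectangle seen as a mildly oblique trapezoid
# inside a 1440x1080 frame (camera tilted off-nadir).
_DEFAULT_CAMERA_QUAD = ((220.0, 130.0), (1250.0, 160.0), (1330.0, 960.0), (130.0, 920.0))


@dataclass(frozen=True)
class SimConfig:
    """Arena, camera, kinematics and noise of one simulated recording.

    Kinematic defaults target a slow-moving poultry flock: mean speed
    0.05 m/s inside a hard 0-0.21 m/s envelope, strong heading persistence.
    """

    arena: tuple[float, float] = (4.0, 3.0)  # (width, height) m
    n_birds: int = 5
    duration_frames: int = 360
    fps: float = 18.0
    frame_size: tuple[int, int] = (1440, 1080)
    mean_speed: float = 0.05  # m/s
    speed_bounds: tuple[float, float] = (0.0, 0.21)  # m/s
    heading_persistence: float = 0.9  # kappa in [0, 1]; 1 = straight line
    turn_sigma: float = 0.6  # rad, std of the raw turning noise eta
    speed_sigma: float = 0.005  # m/s per frame, std of the speed random walk
    speed_reversion: float = 0.1  # per-frame pull of speed toward mean_speed
    camera_quad: tuple = _DEFAULT_CAMERA_QUAD
    noise: ObservationModel = field(default_factory=lambda: ObservationModel.preset("noiseless"))
    body_axes_px: tuple[float, float] = (26.0, 16.0)  # ellipse semi-axes for masks/boxes
    initial_positions: tuple | None = None  # ((x, y) m per bird) override
    initial_heading: float | None = None  # rad, common to all birds; random if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise SimConfigError(f"arena extents must be positive, got {self.arena}")
        if not 1 <= self.n_birds <= 20:
            raise SimConfigError(f"n_birds must be in 1..20, got {self.n_birds}")
        if self.duration_frames < 1:
            raise SimConfigError("duration_frames must be >= 1")
        if not self.fps > 0:
            raise SimConfigError(f"fps must be > 0, got {self.fps}")
        lo, hi = self.speed_bounds
        if not (lo <= self.mean_speed <= hi):
            raise SimConfigError(
                f"speed_bounds {self.speed_bounds} must be ordered and contain mean_speed "
                f"{self.mean_speed}"
            )
        if not 0 <= self.heading_persistence <= 1:
            raise SimConfigError("heading_persistence must lie in [0, 1]")
        # 4 birds/m^2 is already an implausibly dense pen; refuse beyond it.
        if self.n_birds / (self.arena[0] * self.arena[1]) > 4.0:
            raise SimConfigError(
                f"{self.n_birds} birds in a {self.arena[0]}x{self.arena[1]} m arena is too dense"
            )
        if self.initial_positions is not None and len(self.initial_positions) != self.n_birds:
            raise SimConfigError("initial_positions must give one (x, y) per bird")

    def arena_corners(self) -> np.ndarray:
        w, h = self.arena
        return np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])

    def camera_homography(self) -> Homography:
        """World (m) -> camera pixel map implied by the camera quad."""
        return fit_homography(self.arena_corners(), self.camera_quad)

    def to_dict(self) -> dict:
        return {
            "arena": list(self.arena),
            "n_birds": self.n_birds,
            "duration_frames": self.duration_frames,
            "fps": self.fps,
            "frame_size": list(self.frame_size),
            "mean_speed": self.mean_speed,
            "speed_bounds": list(self.speed_bounds),
            "heading_persistence": self.heading_persistence,
            "turn_sigma": self.turn_sigma,
            "speed_sigma": self.speed_sigma,
            "speed_reversion": self.speed_reversion,
            "camera_quad": [list(p) for p in self.camera_quad],
            "noise": {
                "centroid_jitter_sigma": self.noise.centroid_jitter_sigma,
                "miss_prob": self.noise.miss_prob,
                "false_positive_rate": self.noise.false_positive_rate,
                "id_swap_prob": self.noise.id_swap_prob,
                "name": self.noise.name,
            },
            "body_axes_px": list(self.body_axes_px),
            "initial_positions": [list(p) for p in self.initial_positions]
            if self.initial_positions is not None else None,
            "initial_heading": self.initial_heading,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "noise" in d:
            n = d["noise"]
            if isinstance(n, str):
                d["noise"] = ObservationModel.preset(n)
            else:
                d["noise"] = ObservationModel(**n)
        for key in ("arena", "frame_size", "speed_bounds", "body_axes_px"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("camera_quad") is not None:
            d["camera_quad"] = tuple(tuple(p) for p in d["camera_quad"])
        if d.get("initial_positions") is not None:
            d["initial_positions"] = tuple(tuple(p) for p in d["initial_positions"])
        return cls(**d)


@dataclass
class GroundTruthSet:
    """Simulated truth: world tracks, per-step speeds and exact pixel tracks."""

    config: SimConfig
    world_positions: np.ndarray  # (n_birds, T, 2) m
    headings: np.ndarray  # (n_birds, T) rad, heading leaving each frame
    step_speeds: np.ndarray  # (n_birds, T-1) m/s, speed of the step t -> t+1
    pixel_tracks: TrackSet  # world tracks mapped through the camera exactly

    @property
    def track_ids(self) -> list[int]:
        return [i + 1 for i in range(self.config.n_birds)]

    def world_tracksets(self) -> TrackSet:
        """World-coordinate tracks as a TrackSet (metres; no boxes)."""
        ts = TrackSet(fps=self.config.fps, frame_size=None)
        n, t_total, _ = self.world_positions.shape
        for i in range(n):
            for t in range(t_total):
                x, y = self.world_positions[i, t]
                ts.add(Detection(frame=t, track_id=i + 1, centroid=(float(x), float(y))))
        return ts


def _bird_rng(seed: int, bird: int) -> np.random.Generator:
    # Fixed per-bird substream so adding a bird never perturbs the others.
    return np.random.default_rng([seed, bird])


def simulate_flock(cfg: SimConfig) -> GroundTruthSet:
    """Run the correlated random walk and project it through the camera.

    Heading evolves as theta_{t+1} = theta_t + (1 - kappa) * eta with
    eta ~ N(0, turn_sigma^2) wrapped to (-pi, pi]; speed follows
    s_{t+1} = s_t + reversion * (mean - s_t) + N(0, speed_sigma^2), clipped
    to the configured bounds.  Walls reflect: the position is mirrored back
    into the arena and the heading component flips, so path length (hence
    speed) is preserved.  Fully reproducible from the seed.
    """
    n, t_total = cfg.n_birds, cfg.duration_frames
    dt = 1.0 / cfg.fps
    w, h = cfg.arena
    lo, hi = cfg.speed_bounds
    kappa = cfg.heading_persistence

    pos = np.zeros((n, t_total, 2))
    headings = np.zeros((n, t_total))
    speeds = np.zeros((n, max(t_total - 1, 1)))

    for i in range(n):
        rng = _bird_rng(cfg.seed, i)
        if cfg.initial_positions is not None:
            p = np.array(cfg.initial_positions[i], dtype=float)
        else:
            margin = 0.05 * min(w, h)
            p = rng.uniform([margin, margin], [w - margin, h - margin])
        theta = cfg.initial_heading if cfg.initial_heading is not None \
            else rng.uniform(-np.pi, np.pi)
        s = float(np.clip(rng.normal(cfg.mean_speed, cfg.speed_sigma), lo, hi))
        pos[i, 0] = p
        headings[i, 0] = theta
        for t in range(t_total - 1):
            speeds[i, t] = s
            q = p + s * dt * np.array([np.cos(theta), np.sin(theta)])
            # Reflective walls: mirror the overshoot, flip the heading component.
            for axis, extent in ((0, w), (1, h)):
                while q[axis] < 0 or q[axis] > extent:
                    if q[axis] < 0:
                        q[axis] = -q[axis]
                    else:
                        q[axis] = 2 * extent - q[axis]
                    theta = (np.pi - theta) if axis == 0 else -theta
            p = q
            eta = rng.normal(0.0, cfg.turn_sigma)
            theta = theta + (1.0 - kappa) * eta
            theta = (theta + np.pi) % (2 * np.pi) - np.pi
            s = float(np.clip(s + cfg.speed_reversion * (cfg.mean_speed - s)
                              + rng.normal(0.0, cfg.speed_sigma), lo, hi))
            pos[i, t + 1] = p
            headings[i, t + 1] = theta
        if t_total == 1:
            speeds[i, 0] = s

    pixel_tracks = project_to_pixels(pos, cfg)
    return GroundTruthSet(
        config=cfg,
        world_positions=pos,
        headings=headings,
        step_speeds=speeds,
        pixel_tracks=pixel_tracks,
    )


def project_to_pixels(world_positions: np.ndarray, cfg: SimConfig) -> TrackSet:
    """Map (n_birds, T, 2) world tracks into camera pixels via the camera quad.

    The exact inverse of calibrating from the same quad and rectifying back;
    each detection carries a nominal bounding box around the projected
    centroid so the MOT CSV stays well-formed.
    """
    cam = cfg.camera_homography()
    n, t_total, _ = world_positions.shape
    ts = TrackSet(fps=cfg.fps, frame_size=cfg.frame_size)
    bw, bh = 2 * cfg.body_axes_px[0], 2 * cfg.body_axes_px[1]
    for i in range(n):
        uv = apply_homography(cam, world_positions[i])
        for t in range(t_total):
            u, v = float(uv[t, 0]), float(uv[t, 1])
            ts.add(
                Detection(
                    frame=t,
                    track_id=i + 1,
                    centroid=(u, v),
                    bbox=(u - bw / 2, v - bh / 2, bw, bh),
                )
            )
    return ts


def degrade(gt_pixels: TrackSet, model: ObservationModel, seed: int,
            frame_size: tuple[int, int] | None = None) -> TrackSet:
    """Corrupt perfect pixel tracks into realistic tracker output.

    Per frame, in order: identity transposition of the two nearest birds
    (persistent from that frame on), centroid jitter, missed detections,
    Poisson false positives with fresh ids.  Reproducible from the seed.
    """
    rng = np.random.default_rng([seed, 104729])
    frame_size = frame_size or gt_pixels.frame_size
    out = TrackSet(fps=gt_pixels.fps, frame_size=gt_pixels.frame_size)
    frames = gt_pixels.by_frame()
    true_ids = sorted(gt_pixels.trajectories)
    label = {tid: tid for tid in true_ids}  # persistent true id -> emitted id
    next_fp_id = (max(true_ids) if true_ids else 0) + 1

    for f in sorted(frames):
        dets = frames[f]
        if model.id_swap_prob > 0 and len(dets) >= 2 \
                and rng.random() < model.id_swap_prob:
            pts = np.array([d.centroid for d in dets])
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            a, b = np.unravel_index(np.argmin(d2), d2.shape)
            ia, ib = dets[a].track_id, dets[b].track_id
            label[ia], label[ib] = label[ib], label[ia]
        for det in dets:
            jitter = rng.normal(0.0, model.centroid_jitter_sigma, size=2) \
                if model.centroid_jitter_sigma > 0 else np.zeros(2)
            dropped = rng.random() < model.miss_prob if model.miss_prob > 0 else False
            if dropped:
                continue
            u, v = det.centroid[0] + jitter[0], det.centroid[1] + jitter[1]
            bbox = None
            if det.bbox is not None:
                bbox = (det.bbox[0] + jitter[0], det.bbox[1] + jitter[1],
                        det.bbox[2], det.bbox[3])
            out.add(replace(det, track_id=label[det.track_id],
                            centroid=(float(u), float(v)), bbox=bbox))
        if model.false_positive_rate > 0:
            k = rng.poisson(model.false_positive_rate)
            for _ in range(int(k)):
                if frame_size is None:
                    raise SimConfigError("false positives require a frame size")
                u = rng.uniform(0, frame_size[0])
                v = rng.uniform(0, frame_size[1])
                out.add(Detection(frame=f, track_id=next_fp_id,
                                  centroid=(float(u), float(v)),
                                  bbox=(float(u) - 5, float(v) - 5, 10.0, 10.0)))
                next_fp_id += 1
    return out


def render_masks(gt: GroundTruthSet, body_axes_px: tuple[float, float] | None = None,
                 frames: Sequence[int] | None = None) -> list[MaskRLE]:
    """Rasterize each bird as a filled ellipse oriented along its motion heading.

    Returns one MaskRLE per bird per requested frame (default: all frames).
    Ellipses are clipped at the frame boundary.
    """
    from skimage.draw import ellipse as sk_ellipse

    cfg = gt.config
    a, b = body_axes_px or cfg.body_axes_px
    if a <= 0 or b <= 0:
        raise SimConfigError(f"ellipse semi-axes must be positive, got {(a, b)}")
    w, h = cfg.frame_size
    cam = cfg.camera_homography()
    frames = range(cfg.duration_frames) if frames is None else frames
    masks: list[MaskRLE] = []
    for t in frames:
        for i in range(cfg.n_birds):
            u, v = apply_homography(cam, gt.world_positions[i, t])
            # Pixel-space heading: project a small step along the world heading.
            theta_w = gt.headings[i, t]
            step = gt.world_positions[i, t] + 1e-3 * np.array(
                [np.cos(theta_w), np.sin(theta_w)])
            u2, v2 = apply_homography(cam, step)
            theta_px = np.arctan2(v2 - v, u2 - u)
            raster = np.zeros((h, w), dtype=np.uint8)
            # skimage rotation is counter-clockwise in (row, col) space.
            rr, cc = sk_ellipse(v, u, b, a, shape=(h, w), rotation=-theta_px)
            raster[rr, cc] = 1
            masks.append(encode_rle(raster, frame=int(t), track_id=i + 1))
    return masks
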