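"""Planar projective calibration between the camera view and a metric top-down view.

A single overhead (but oblique) camera observes animals moving on a flat
floor.  Four pixel corners of a rectangle of known physical size determine a
3x3 homography that rectifies the camera view into a top-down plane in which
one pixel corresponds to a fixed physical distance ``pixel_scale_w`` (m/px).
Speeds measured as pixel displacements in that plane therefore convert to
metres per second by a single multiplicative constant.

The homography is estimated with a normalized direct linear transform
(Hartley-style isotropic normalization of both point sets before solving the
8x9 homogeneous system), the minimal exact solver for four correspondences
in general position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "CalibrationError",
    "Homography",
    "CalibrationConfig",
    "fit_homography",
    "apply_homography",
    "invert_homography",
    "compute_pixel_scale",
    "load_calibration",
    "save_calibration",
]


class CalibrationError(ValueError):
    """Raised for degenerate point configurations or invalid calibration input."""


# Relative tolerance below which three points are declared collinear.
_COLLINEAR_RTOL = 1e-9


@dataclass(frozen=True)
class Homography:
    """A 3x3 invertible projective map plus the top-down metre-per-pixel scale.

    Attributes
    ----------
    matrix
        3x3 real matrix, normalized so that ``matrix[2, 2] == 1``.
    pixel_scale_w
        Physical distance represented by one pixel of the top-down view,
        in metres per pixel.  Defaults to 1.0, i.e. the destination plane
        is already metric.
    """

    matrix: np.ndarray
    pixel_scale_w: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise CalibrationError(f"homography matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise CalibrationError("homography matrix contains non-finite entries")
        if m[2, 2] == 0.0:
            raise CalibrationError("homography normalization entry is zero")
        if m[2, 2] != 1.0:
            m = m / m[2, 2]
        if abs(np.linalg.det(m)) < 1e-12:
            raise CalibrationError("homography matrix is singular")
        if not self.pixel_scale_w > 0:
            raise CalibrationError(f"pixel_scale_w must be > 0, got {self.pixel_scale_w}")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, pixel_scale_w: float = 1.0) -> "Homography":
        return cls(np.eye(3), pixel_scale_w)


def _as_points(points: Sequence[Sequence[float]], name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise CalibrationError(f"{name} must be an (n, 2) array of points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise CalibrationError(f"{name} contains non-finite coordinates")
    return pts


def _has_collinear_triple(pts: np.ndarray) -> bool:
    n = len(pts)
    scale = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1e-300)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
                if area2 <= _COLLINEAR_RTOL * scale * scale:
                    return True
    return False


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform sending pts to centroid 0, RMS distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    s = np.sqrt(2.0) / rms if rms > 0 else 1.0
    return np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )


def fit_homography(
    src: Sequence[Sequence[float]],
    dst: Sequence[Sequence[float]],
    pixel_scale_w: float = 1.0,
) -> Homography:
    """Estimate the exact homography mapping 4 source points onto 4 destination points.

    Parameters
    ----------
    src, dst
        Four 2-D points each, listed in the same cyclic order, no three
        collinear on either side.
    pixel_scale_w
        Metres per pixel of the destination plane, stored on the result.

    Returns
    -------
    Homography
        Normalized (bottom-right entry 1) matrix reproducing every
        correspondence to better than 1e-8.

    Raises
    ------
    CalibrationError
        If not exactly 4 points are given on each side, or three of them
        are collinear (degenerate configuration).
    """
    s = _as_points(src, "src")
    d = _as_points(dst, "dst")
    if s.shape[0] != 4 or d.shape[0] != 4:
        raise CalibrationError(
            f"exactly 4 point correspondences required, got {s.shape[0]} src / {d.shape[0]} dst"
        )
    if _has_collinear_triple(s):
        raise CalibrationError("degenerate calibration: 3 or more source points are collinear")
    if _has_collinear_triple(d):
        raise CalibrationError("degenerate calibration: 3 or more destination points are collinear")

    ts, td = _normalization(s), _normalization(d)
    sn = (ts @ np.column_stack([s, np.ones(4)]).T).T[:, :2]
    dn = (td @ np.column_stack([d, np.ones(4)]).T).T[:, :2]

    # Direct linear transform: each correspondence contributes two rows of
    # the homogeneous system A h = 0 for the 9-vector h.
    a = np.zeros((8, 9))
    for i, ((x, y), (u, v)) in enumerate(zip(sn, dn)):
        a[2 * i] = [-x, -y, -1, 0, 0, 0, u * x, u * y, u]
        a[2 * i + 1] = [0, 0, 0, -x, -y, -1, v * x, v * y, v]
    _, sv, vt = np.linalg.svd(a)
    h_n = vt[-1].reshape(3, 3)
    h = np.linalg.inv(td) @ h_n @ ts
    if abs(h[2, 2]) < 1e-14 * np.abs(h).max():
        raise CalibrationError("fitted homography is not normalizable (affine part vanishes)")
    return Homography(h / h[2, 2], pixel_scale_w)


def apply_homography(h: Homography, point: Sequence[float]) -> np.ndarray:
    """Map a single 2-D point (or an (n, 2) array of points) through ``h``.

    Dehomogenizes the projective image; raises ``CalibrationError`` if a
    point maps onto the line at infinity.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    if pts.shape[1] != 2:
        raise CalibrationError(f"points must have 2 coordinates, got shape {p.shape}")
    hom = h.matrix @ np.column_stack([pts, np.ones(len(pts))]).T
    w = hom[2]
    if np.any(np.abs(w) < 1e-300) or not np.all(np.isfinite(w)):
        raise CalibrationError("point maps to the line at infinity under this homography")
    out = (hom[:2] / w).T
    return out[0] if single else out


def invert_homography(h: Homography) -> Homography:
    """Return the inverse map, preserving ``pixel_scale_w``."""
    inv = np.linalg.inv(h.matrix)
    return Homography(inv / inv[2, 2], h.pixel_scale_w)


def compute_pixel_scale(rect_physical_extent_m: float, rect_topdown_extent_px: float) -> float:
    """Metres per top-down pixel: physical extent of the reference rectangle
    divided by the extent of its image in the rectified view."""
    if not rect_physical_extent_m > 0:
        raise CalibrationError(f"physical extent must be > 0, got {rect_physical_extent_m}")
    if not rect_topdown_extent_px > 0:
        raise CalibrationError(f"top-down extent must be > 0, got {rect_topdown_extent_px}")
    return rect_physical_extent_m / rect_topdown_extent_px


@dataclass
class CalibrationConfig:
    """User-supplied calibration: pixel corners of a floor rectangle of known size.

    ``source_points`` are the four pixel ``[u, v]`` corners of the reference
    rectangle in the camera frame, in cyclic order starting at the world
    origin corner and proceeding (+x, +x+y, +y).  ``topdown_size_px``, when
    given, sets the raster size of the rectified view; otherwise the
    destination plane is metric and ``pixel_scale_w`` is 1.
    """

    source_points: list = field(default_factory=list)
    rect_width_m: float = 1.0
    rect_height_m: float = 1.0
    topdown_size_px: list | None = None

    def to_dict(self) -> dict:
        d = {
            "source_points": [[float(u), float(v)] for u, v in self.source_points],
            "rect_width_m": float(self.rect_width_m),
            "rect_height_m": float(self.rect_height_m),
        }
        if self.topdown_size_px is not None:
            d["topdown_size_px"] = [float(self.topdown_size_px[0]), float(self.topdown_size_px[1])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        return cls(
            source_points=[[float(u), float(v)] for u, v in d["source_points"]],
            rect_width_m=float(d["rect_width_m"]),
            rect_height_m=float(d["rect_height_m"]),
            topdown_size_px=list(d["topdown_size_px"]) if d.get("topdown_size_px") else None,
        )

    def destination_points(self) -> np.ndarray:
        """Corners of the rectangle in the top-down plane (px if a raster
        size is configured, metres otherwise), matching source order."""
        if self.topdown_size_px is not None:
            w, h = self.topdown_size_px
        else:
            w, h = self.rect_width_m, self.rect_height_m
        return np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])

    def fit(self) -> Homography:
        """Fit the camera-to-top-down homography and derive ``pixel_scale_w``."""
        if self.rect_width_m <= 0 or self.rect_height_m <= 0:
            raise CalibrationError("rectangle physical dimensions must be positive")
        if self.topdown_size_px is None:
            scale = 1.0
        else:
            scale = compute_pixel_scale(self.rect_width_m, self.topdown_size_px[0])
            scale_v = compute_pixel_scale(self.rect_height_m, self.topdown_size_px[1])
            if abs(scale - scale_v) > 1e-9 * max(scale, scale_v):
                raise CalibrationError(
                    "anisotropic top-down raster: horizontal scale "
                    f"{scale} m/px differs from vertical {scale_v} m/px"
                )
        return fit_homography(self.source_points, self.destination_points(), pixel_scale_w=scale)


def load_calibration(path: str | Path) -> CalibrationConfig:
    """Read a calibration config from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return CalibrationConfig.from_dict(yaml.safe_load(text))
    return CalibrationConfig.from_dict(json.loads(text))


def save_calibration(cfg: CalibrationConfig, path: str | Path) -> None:
    """Write a calibration config; round-trips bit-exactly through load_calibration."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    else:
        path.write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
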