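"""Data model and I/O for per-frame detections, identity trajectories and masks.

Tracks interchange in the MOTChallenge CSV dialect::

    frame, id, bb_left, bb_top, bb_width, bb_height[, conf, x, y, z]

with 1-based frame numbers on disk and 0-based frame indices in memory.
Segmentation masks are accepted either as label-image PNGs (pixel value =
track id, 0 = background) or as run-length-encoded JSON; the canonical
in-memory form is :class:`MaskRLE` with row-major runs alternating
background/foreground, starting with background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from PIL import Image

__all__ = [
    "TrackFormatError",
    "Detection",
    "Trajectory",
    "TrackSet",
    "MaskRLE",
    "read_mot",
    "write_mot",
    "encode_rle",
    "decode_rle",
    "mask_centroid",
    "read_mask_json",
    "write_mask_json",
    "read_label_png",
    "write_label_png",
]


class TrackFormatError(ValueError):
    """Malformed track or mask data."""


@dataclass(frozen=True)
class Detection:
    """One object observation in one frame.

    ``centroid`` is the tracked pixel point ``(u, v)``; when a bounding box
    is present the centroid defaults to the box centre.  ``frame`` is
    0-based.
    """

    frame: int
    track_id: int
    centroid: tuple[float, float]
    bbox: tuple[float, float, float, float] | None = None  # left, top, w, h (px)
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise TrackFormatError(f"frame index must be >= 0, got {self.frame}")
        if self.track_id < 1:
            raise TrackFormatError(f"track_id must be >= 1, got {self.track_id}")
        if self.bbox is not None and (self.bbox[2] <= 0 or self.bbox[3] <= 0):
            raise TrackFormatError(f"bbox width/height must be > 0, got {self.bbox}")
        if not all(np.isfinite(self.centroid)):
            raise TrackFormatError(f"non-finite centroid {self.centroid}")


@dataclass
class Trajectory:
    """Ordered detections of one identity; frames strictly increasing."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    def append(self, det: Detection) -> None:
        if det.track_id != self.track_id:
            raise TrackFormatError(
                f"detection id {det.track_id} appended to trajectory {self.track_id}"
            )
        if self.detections and det.frame <= self.detections[-1].frame:
            raise TrackFormatError(
                f"track {self.track_id}: duplicate or out-of-order frame {det.frame}"
            )
        self.detections.append(det)

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self) -> Iterator[Detection]:
        return iter(self.detections)


@dataclass
class TrackSet:
    """All trajectories of one recording, plus frame rate and frame size."""

    trajectories: dict[int, Trajectory] = field(default_factory=dict)
    fps: float = 18.0
    frame_size: tuple[int, int] | None = None  # (width, height) px

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise TrackFormatError(f"fps must be > 0, got {self.fps}")

    def add(self, det: Detection) -> None:
        self.trajectories.setdefault(det.track_id, Trajectory(det.track_id)).append(det)

    def by_frame(self) -> dict[int, list[Detection]]:
        """Group detections per frame, ordered by track id within a frame."""
        frames: dict[int, list[Detection]] = {}
        for tid in sorted(self.trajectories):
            for det in self.trajectories[tid]:
                frames.setdefault(det.frame, []).append(det)
        return dict(sorted(frames.items()))

    def all_detections(self) -> list[Detection]:
        return [d for f in self.by_frame().values() for d in f]

    @property
    def n_detections(self) -> int:
        return sum(len(t) for t in self.trajectories.values())

    @property
    def frame_range(self) -> tuple[int, int] | None:
        frames = [f for t in self.trajectories.values() for f in t.frames]
        return (min(frames), max(frames)) if frames else None

    def map_centroids(self, fn) -> "TrackSet":
        """Return a new TrackSet with every centroid replaced by fn(centroid).

        Bounding boxes are dropped: an axis-aligned box is not preserved by a
        general plane-to-plane map.
        """
        out = TrackSet(fps=self.fps, frame_size=None)
        for tid in sorted(self.trajectories):
            for det in self.trajectories[tid]:
                u, v = fn(np.asarray(det.centroid, dtype=float))
                out.add(replace(det, centroid=(float(u), float(v)), bbox=None))
        return out


def read_mot(path: str | Path, fps: float = 18.0,
             frame_size: tuple[int, int] | None = None) -> TrackSet:
    """Parse a MOTChallenge CSV file into a TrackSet.

    File frame numbers are 1-based and converted to 0-based indices.  Rows
    with ``id == -1`` (raw detections without identity) are rejected, as are
    nonpositive box dimensions.  Lines starting with ``#`` are ignored.
    """
    ts = TrackSet(fps=fps, frame_size=frame_size)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 6:
                raise TrackFormatError(
                    f"{path}:{lineno}: expected >= 6 comma-separated fields, got {len(parts)}"
                )
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                left, top, w, h = (float(x) for x in parts[2:6])
                conf = float(parts[6]) if len(parts) > 6 else None
            except ValueError as exc:
                raise TrackFormatError(f"{path}:{lineno}: unparseable row: {exc}") from exc
            if tid == -1:
                raise TrackFormatError(
                    f"{path}:{lineno}: id -1 (detection without identity) not allowed in tracking mode"
                )
            if frame < 1:
                raise TrackFormatError(f"{path}:{lineno}: frame numbers on disk are 1-based, got {frame}")
            if w <= 0 or h <= 0:
                raise TrackFormatError(f"{path}:{lineno}: nonpositive box dimensions {w}x{h}")
            ts.add(
                Detection(
                    frame=frame - 1,
                    track_id=tid,
                    centroid=(left + w / 2.0, top + h / 2.0),
                    bbox=(left, top, w, h),
                    confidence=conf,
                )
            )
    return ts


def write_mot(ts: TrackSet, path: str | Path, header: str | None = None) -> None:
    """Write a TrackSet in the MOTChallenge dialect (frames re-emitted 1-based).

    Detections without a bounding box are written as a degenerate 1x1 box
    centred on the centroid, which read_mot inverts exactly.
    """
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for frame, dets in ts.by_frame().items():
        for det in dets:
            if det.bbox is not None:
                left, top, w, h = det.bbox
            else:
                left, top, w, h = det.centroid[0] - 0.5, det.centroid[1] - 0.5, 1.0, 1.0
            conf = det.confidence if det.confidence is not None else 1
            lines.append(
                f"{frame + 1},{det.track_id},{_fmt(left)},{_fmt(top)},{_fmt(w)},{_fmt(h)},"
                f"{_fmt(conf)},-1,-1,-1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _fmt(x: float) -> str:
    """Compact float formatting: integral values print without a decimal point."""
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else repr(xf)


# ---------------------------------------------------------------------------
# Masks


@dataclass(frozen=True)
class MaskRLE:
    """Run-length-encoded binary instance mask for one track in one frame.

    ``counts`` are row-major run lengths alternating background/foreground,
    starting with background; they sum to ``width * height`` of
    ``frame_size = (width, height)``.
    """

    frame: int
    track_id: int
    frame_size: tuple[int, int]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        w, h = self.frame_size
        if any(c < 0 for c in self.counts):
            raise TrackFormatError("negative run length")
        if sum(self.counts) != w * h:
            raise TrackFormatError(
                f"run lengths sum to {sum(self.counts)}, expected {w}*{h}={w * h}"
            )

    @property
    def area(self) -> int:
        return sum(self.counts[1::2])


def encode_rle(raster: np.ndarray, frame: int = 0, track_id: int = 1) -> MaskRLE:
    """Encode a binary (H, W) raster into canonical RLE.

    Canonical form: first run is background (possibly length 0), no interior
    zero-length runs, no trailing zero run.
    """
    r = np.asarray(raster)
    if r.ndim != 2:
        raise TrackFormatError(f"raster must be 2-D, got shape {r.shape}")
    flat = (r != 0).ravel().astype(np.int8)
    h, w = r.shape
    if flat.size == 0:
        raise TrackFormatError("empty raster")
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:  # canonical encoding starts with a background run
        runs = [0] + runs
    return MaskRLE(frame=frame, track_id=track_id, frame_size=(w, h), counts=tuple(runs))


def decode_rle(m: MaskRLE) -> np.ndarray:
    """Decode to a binary uint8 raster of shape (height, width)."""
    w, h = m.frame_size
    flat = np.zeros(w * h, dtype=np.uint8)
    pos = 0
    val = 0
    for run in m.counts:
        if val:
            flat[pos : pos + run] = 1
        pos += run
        val ^= 1
    return flat.reshape(h, w)


def mask_centroid(m: MaskRLE) -> tuple[float, float]:
    """Arithmetic mean (u, v) of the foreground pixel coordinates.

    Computed directly from the runs without materializing the raster.
    Raises on an empty mask.
    """
    w, _ = m.frame_size
    total = 0
    sum_u = 0
    sum_v = 0
    pos = 0
    val = 0
    for run in m.counts:
        if val and run:
            idx = np.arange(pos, pos + run)
            sum_u += int((idx % w).sum())
            sum_v += int((idx // w).sum())
            total += run
        pos += run
        val ^= 1
    if total == 0:
        raise TrackFormatError(f"empty mask (frame {m.frame}, track {m.track_id})")
    return (sum_u / total, sum_v / total)


def write_mask_json(masks: Iterable[MaskRLE], path: str | Path) -> None:
    """Write masks as a JSON list of ``{frame, id, size: [h, w], counts}``."""
    records = [
        {
            "frame": m.frame,
            "id": m.track_id,
            "size": [m.frame_size[1], m.frame_size[0]],
            "counts": list(m.counts),
        }
        for m in masks
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_mask_json(path: str | Path) -> list[MaskRLE]:
    records = json.loads(Path(path).read_text())
    out = []
    for rec in records:
        h, w = rec["size"]
        out.append(
            MaskRLE(
                frame=int(rec["frame"]),
                track_id=int(rec["id"]),
                frame_size=(int(w), int(h)),
                counts=tuple(int(c) for c in rec["counts"]),
            )
        )
    return out


def write_label_png(masks: Iterable[MaskRLE], path: str | Path) -> None:
    """Render one frame's instance masks into a label PNG (pixel = track id).

    Overlapping instances resolve to the higher track id.  All masks must
    share frame index and size.
    """
    masks = list(masks)
    if not masks:
        raise TrackFormatError("no masks to write")
    size = masks[0].frame_size
    if any(m.frame_size != size or m.frame != masks[0].frame for m in masks):
        raise TrackFormatError("label PNG requires masks from one frame with one size")
    w, h = size
    label = np.zeros((h, w), dtype=np.uint16)
    for m in sorted(masks, key=lambda m: m.track_id):
        label[decode_rle(m) != 0] = m.track_id
    Image.fromarray(label).save(Path(path))


def read_label_png(path: str | Path, frame: int = 0) -> list[MaskRLE]:
    """Split a label PNG (pixel value = track id, 0 = background) into per-id RLE masks."""
    label = np.asarray(Image.open(Path(path)))
    if label.ndim != 2:
        raise TrackFormatError(f"label PNG must be single-channel, got shape {label.shape}")
    return [
        encode_rle(label == tid, frame=frame, track_id=int(tid))
        for tid in np.unique(label)
        if tid != 0
    ]
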