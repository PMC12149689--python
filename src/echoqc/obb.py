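"""Oriented bounding boxes, circular smooth angle labels, rotated IoU/NMS.

Coordinate conventions: image pixels, x right, y down, origin at the top-left
corner.  ``theta`` is the angle of the box's *long* side against the +x axis,
in degrees in [0, 180) — so a visually vertical left-ventricle major axis is
theta = 90 regardless of the y-down orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "StructureLabel",
    "ESSENTIAL_STRUCTURES",
    "OrientedBox",
    "Detection",
    "StructureCheck",
    "csl_encode",
    "csl_decode",
    "rotated_iou",
    "rotated_nms",
    "check_structures",
    "detections_to_json",
    "detections_from_json",
]


class StructureLabel(str, Enum):
    """The seven anatomical structures of the apical four-chamber view."""

    LV = "LV"
    RV = "RV"
    LA = "LA"
    RA = "RA"
    IVS = "IVS"
    MV = "MV"
    TV = "TV"


#: Structures that must be visible in both ED and ES frames.  The mitral and
#: tricuspid valves are exempt (individual variability).
ESSENTIAL_STRUCTURES = frozenset(
    {StructureLabel.LV, StructureLabel.RV, StructureLabel.LA,
     StructureLabel.RA, StructureLabel.IVS}
)


@dataclass(frozen=True)
class OrientedBox:
    """Rotated rectangle: center, long side ``w``, short side ``h``, angle."""

    cx: float
    cy: float
    w: float
    h: float
    theta: float  # degrees in [0, 180), long side vs +x axis

    def __post_init__(self) -> None:
        if not (self.w >= self.h > 0):
            raise ValueError(f"require w >= h > 0, got w={self.w}, h={self.h}")
        if not (0.0 <= self.theta < 180.0):
            raise ValueError(f"theta must be in [0, 180), got {self.theta}")

    def corners(self) -> np.ndarray:
        """(4, 2) corner coordinates, counter-clockwise in the y-down frame."""
        t = np.deg2rad(self.theta)
        u = np.array([np.cos(t), np.sin(t)])   # long-side direction
        v = np.array([-np.sin(t), np.cos(t)])  # short-side direction
        c = np.array([self.cx, self.cy])
        hw, hh = self.w / 2.0, self.h / 2.0
        return np.array([
            c - hw * u - hh * v,
            c + hw * u - hh * v,
            c + hw * u + hh * v,
            c - hw * u + hh * v,
        ])

    def polygon(self) -> Polygon:
        return Polygon(self.corners())

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class Detection:
    box: OrientedBox
    label: StructureLabel
    confidence: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", StructureLabel(self.label))
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class StructureCheck:
    """Result of the essential-structure visibility criterion."""

    passed: bool
    missing: tuple  # of (StructureLabel, "ED"|"ES")

    def __post_init__(self) -> None:
        assert self.passed == (len(self.missing) == 0)


def csl_encode(theta: float, window_radius: int = 6, n_bins: int = 180) -> np.ndarray:
    """Encode an angle as a circular smooth label vector.

    The vector is 1 at the bin of ``round(theta)`` and falls off as a
    Gaussian ``exp(-d^2 / (2 r^2))`` of circular bin distance ``d`` up to
    ``window_radius`` bins away (wrapping across the 0/last-bin boundary);
    0 elsewhere.  ``window_radius == 0`` gives a one-hot vector.
    """
    if window_radius < 0:
        raise ValueError("window_radius must be >= 0")
    if not (0.0 <= theta < 180.0):
        raise ValueError(f"theta must be in [0, 180), got {theta}")
    if n_bins <= 0 or 180 % n_bins:
        raise ValueError("n_bins must divide 180 evenly")
    scale = n_bins / 180.0
    center = int(round(theta * scale)) % n_bins
    bins = np.arange(n_bins)
    d = np.abs(bins - center)
    d = np.minimum(d, n_bins - d)  # circular distance
    vec = np.zeros(n_bins, dtype=float)
    if window_radius == 0:
        vec[center] = 1.0
        return vec
    inside = d <= window_radius
    vec[inside] = np.exp(-(d[inside] ** 2) / (2.0 * window_radius**2))
    vec[center] = 1.0
    return vec


def csl_decode(scores: Sequence[float], n_bins: int | None = None) -> float:
    """Map a circular-smooth-label score vector back to degrees (argmax bin).

    Ties resolve to the smallest bin index.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    n = scores.shape[0] if n_bins is None else n_bins
    return float(int(np.argmax(scores)) * (180.0 / n))


def rotated_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Intersection-over-union of two rotated rectangles via polygon clipping."""
    pa, pb = a.polygon(), b.polygon()
    inter = pa.intersection(pb).area
    if inter == 0.0:
        return 0.0
    union = pa.area + pb.area - inter
    return float(inter / union)


def rotated_nms(dets: Sequence[Detection], iou_thresh: float = 0.5) -> list[Detection]:
    """Greedy class-wise non-maximum suppression, descending confidence.

    Ties in confidence keep the earlier detection first (stable).
    """
    if not (0.0 < iou_thresh <= 1.0):
        raise ValueError("iou_thresh must be in (0, 1]")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    keep: list[int] = []
    for i in order:
        suppressed = any(
            dets[j].label == dets[i].label
            and rotated_iou(dets[j].box, dets[i].box) >= iou_thresh
            for j in keep
        )
        if not suppressed:
            keep.append(i)
    keep.sort()
    return [dets[i] for i in keep]


def check_structures(
    dets_ed: Sequence[Detection],
    dets_es: Sequence[Detection],
    conf_thresh: float = 0.25,
) -> StructureCheck:
    """Essential structures {LV, RV, LA, RA, IVS} must be visible in both the
    ED and ES frames; MV/TV never affect the result."""
    missing: list[tuple[StructureLabel, str]] = []
    for role, dets in (("ED", dets_ed), ("ES", dets_es)):
        visible = {d.label for d in dets if d.confidence >= conf_thresh}
        for label in sorted(ESSENTIAL_STRUCTURES, key=lambda s: s.value):
            if label not in visible:
                missing.append((label, role))
    return StructureCheck(passed=not missing, missing=tuple(missing))


# ---------------------------------------------------------------------------
# JSON interchange.  Per frame:
#   {"frame": int, "detections": [{"label", "cx", "cy", "w", "h", "theta", "conf"}]}
# Ground truth uses the same schema with "conf" omitted (read back as 1.0).


def detections_to_json(frames: dict[int, Sequence[Detection]], with_conf: bool = True) -> str:
    out = []
    for frame in sorted(frames):
        entry = {"frame": int(frame), "detections": []}
        for d in frames[frame]:
            rec = {
                "label": d.label.value,
                "cx": round(float(d.box.cx), 4),
                "cy": round(float(d.box.cy), 4),
                "w": round(float(d.box.w), 4),
                "h": round(float(d.box.h), 4),
                "theta": round(float(d.box.theta), 4),
            }
            if with_conf:
                rec["conf"] = round(float(d.confidence), 6)
            entry["detections"].append(rec)
        out.append(entry)
    return json.dumps(out, indent=1)


def detections_from_json(text: str) -> dict[int, list[Detection]]:
    frames: dict[int, list[Detection]] = {}
    for entry in json.loads(text):
        dets = [
            Detection(
                box=OrientedBox(r["cx"], r["cy"], r["w"], r["h"], r["theta"] % 180.0),
                label=StructureLabel(r["label"]),
                confidence=float(r.get("conf", 1.0)),
            )
            for r in entry["detections"]
        ]
        frames[int(entry["frame"])] = dets
    return frames
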