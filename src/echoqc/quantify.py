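"""Depth and cardiac-axis quantification from oriented detections.

Both parameters are measured on the ES target frame of a cycle:

* depth ``D = h2 / h1`` — the vertical extent of the detected heart
  silhouette over the image height; normal range default (0.5, 0.75).
* cardiac-axis angle ``C`` — the angle of the left-ventricle box's major
  axis against the x-axis, degrees; normal range default (75, 95).

Open intervals: boundary values fail.  Empty/missing detections yield a
"not computable" result, which downstream scoring treats as a criterion
failure with an explanatory reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .obb import Detection, StructureLabel

__all__ = [
    "DepthResult",
    "CaaResult",
    "depth_ratio",
    "caa_angle",
    "DEPTH_RANGE_DEFAULT",
    "CAA_RANGE_DEFAULT",
    "DEPTH_RANGE_PROTOCOL",
    "CAA_RANGE_PROTOCOL",
]

#: Operational thresholds (statistical, on D = h2/h1 and C = theta).
DEPTH_RANGE_DEFAULT = (0.5, 0.75)
CAA_RANGE_DEFAULT = (75.0, 95.0)

#: Protocol-sheet presets: silhouette covering 2/3..4/5 of the sector, and an
#: axis within +/-20 degrees of vertical.
DEPTH_RANGE_PROTOCOL = (2.0 / 3.0, 4.0 / 5.0)
CAA_RANGE_PROTOCOL = (70.0, 110.0)


@dataclass(frozen=True)
class DepthResult:
    d: float | None
    h2: float | None
    h1: float
    passed: bool

    @property
    def computable(self) -> bool:
        return self.d is not None


@dataclass(frozen=True)
class CaaResult:
    c: float | None
    passed: bool

    @property
    def computable(self) -> bool:
        return self.c is not None


def depth_ratio(
    dets: Sequence[Detection],
    image_height: float,
    lo: float = DEPTH_RANGE_DEFAULT[0],
    hi: float = DEPTH_RANGE_DEFAULT[1],
    h2_mode: Literal["union", "max_single"] = "union",
) -> DepthResult:
    """Heart-silhouette-to-image height ratio D = h2/h1.

    ``h2_mode='union'`` (default) measures the vertical extent of the union
    of all detection corner polygons; ``'max_single'`` takes the tallest
    single box instead.
    """
    if image_height <= 0:
        raise ValueError("image_height must be positive")
    if not dets:
        return DepthResult(d=None, h2=None, h1=float(image_height), passed=False)
    if h2_mode == "union":
        ys = np.concatenate([d.box.corners()[:, 1] for d in dets])
        h2 = float(ys.max() - ys.min())
    elif h2_mode == "max_single":
        h2 = max(float(np.ptp(d.box.corners()[:, 1])) for d in dets)
    else:
        raise ValueError(f"unknown h2_mode {h2_mode!r}")
    d = h2 / float(image_height)
    return DepthResult(d=d, h2=h2, h1=float(image_height), passed=bool(lo < d < hi))


def caa_angle(
    dets: Sequence[Detection],
    lo: float = CAA_RANGE_DEFAULT[0],
    hi: float = CAA_RANGE_DEFAULT[1],
) -> CaaResult:
    """Cardiac-axis angle C from the highest-confidence LV detection."""
    lv = [d for d in dets if d.label is StructureLabel.LV]
    if not lv:
        return CaaResult(c=None, passed=False)
    best = max(lv, key=lambda d: d.confidence)
    c = float(best.box.theta)
    return CaaResult(c=c, passed=bool(lo < c < hi))
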