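"""Left-ventricular volume curve (LVVC) construction and cardiac phase analysis.

The per-frame scalar volume proxy lives in [-1, 1]: peaks (+1) mark
end-diastole (ED), troughs (-1) mark end-systole (ES).  Ground-truth curves
are built from annotated keyframes with a piecewise sinusoid; predicted
curves are inverted back into keyframes by local-extremum detection, and
alternating keyframe triples define complete cardiac cycles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phase",
    "KeyframeLabel",
    "PhaseCurve",
    "CardiacCycle",
    "QCTargets",
    "ValidationError",
    "validate_labels",
    "lvvc_ground_truth",
    "extract_keyframes",
    "find_complete_cycles",
    "select_qc_targets",
    "labels_to_json",
    "labels_from_json",
]


class ValidationError(ValueError):
    """Raised when annotations violate the documented invariants."""


class Phase(str, Enum):
    ED = "ED"
    ES = "ES"

    @property
    def opposite(self) -> "Phase":
        return Phase.ES if self is Phase.ED else Phase.ED


@dataclass(frozen=True, order=True)
class KeyframeLabel:
    """A labeled cardiac keyframe: 0-based frame index plus its phase."""

    frame_index: int
    phase: Phase

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        object.__setattr__(self, "phase", Phase(self.phase))


@dataclass
class PhaseCurve:
    """Per-frame volume proxy in [-1, 1] with a supervision mask.

    ``mask[t]`` is False for frames outside the labeled keyframe span, where
    the ground-truth construction defines no value (such frames are excluded
    from any training loss).
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("PhaseCurve values must be 1-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask length must equal curve length")
        supervised = self.values[self.mask]
        if supervised.size and (supervised.min() < -1 - 1e-9 or supervised.max() > 1 + 1e-9):
            raise ValidationError("supervised curve values must lie in [-1, 1]")

    def __len__(self) -> int:
        return int(self.values.shape[0])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "value": self.values,
                "mask": self.mask.astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhaseCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(values=df["value"].to_numpy(), mask=df["mask"].to_numpy(dtype=bool))


class CyclePattern(str, Enum):
    ED_ES_ED = "ED_ES_ED"
    ES_ED_ES = "ES_ED_ES"


@dataclass(frozen=True)
class CardiacCycle:
    """An alternating keyframe triple: start/mid/end with start.phase == end.phase."""

    start: KeyframeLabel
    mid: KeyframeLabel
    end: KeyframeLabel

    def __post_init__(self) -> None:
        if self.start.phase != self.end.phase or self.start.phase == self.mid.phase:
            raise ValidationError("cycle phases must alternate (X-Y-X)")
        if not (self.start.frame_index < self.mid.frame_index < self.end.frame_index):
            raise ValidationError("cycle keyframes must be strictly increasing")

    @property
    def pattern(self) -> CyclePattern:
        return CyclePattern.ED_ES_ED if self.start.phase is Phase.ED else CyclePattern.ES_ED_ES

    @property
    def keyframes(self) -> tuple[KeyframeLabel, KeyframeLabel, KeyframeLabel]:
        return (self.start, self.mid, self.end)


@dataclass(frozen=True)
class QCTargets:
    """The ED and ES frames of one cycle on which QC criteria are evaluated."""

    ed_frame: int
    es_frame: int
    cycle: CardiacCycle

    def __post_init__(self) -> None:
        members = {kf.frame_index for kf in self.cycle.keyframes}
        if self.ed_frame not in members or self.es_frame not in members:
            raise ValidationError("QC target frames must be keyframes of the cycle")


def validate_labels(labels: Sequence[KeyframeLabel]) -> list[KeyframeLabel]:
    """Check ordering/alternation invariants and return the list.

    Raises :class:`ValidationError` on duplicate indices, non-increasing order
    or two consecutive labels sharing a phase.
    """
    labels = [
        kf if isinstance(kf, KeyframeLabel) else KeyframeLabel(kf[0], Phase(kf[1]))
        for kf in labels
    ]
    for prev, cur in zip(labels, labels[1:]):
        if cur.frame_index <= prev.frame_index:
            raise ValidationError(
                f"keyframes must be strictly increasing: {prev.frame_index} then {cur.frame_index}"
            )
        if cur.phase == prev.phase:
            raise ValidationError(
                f"keyframe phases must alternate: {prev.phase.value} repeated at "
                f"frame {cur.frame_index}"
            )
    return labels


def _segment_value(x: np.ndarray, f1: KeyframeLabel, f2: KeyframeLabel) -> np.ndarray:
    """Evaluate the sinusoid on one half-phase segment [f1, f2]."""
    if f1.phase is Phase.ES:  # diastole: ES -> ED, volume rises to +1
        f_es, f_ed = float(f1.frame_index), float(f2.frame_index)
        return np.sin(1.5 * np.pi - np.pi * (f_es - x) / (f_ed - f_es))
    # systole: ED -> ES, volume falls to -1
    f_ed, f_es = float(f1.frame_index), float(f2.frame_index)
    return np.sin(1.5 * np.pi + np.pi * (x - f_es) / (f_es - f_ed))


def lvvc_ground_truth(
    labels: Sequence[KeyframeLabel], n_frames: int, extrapolate: bool = False
) -> PhaseCurve:
    """Build the ground-truth volume curve from keyframe labels.

    Each half-phase between consecutive labels is a quarter-period sinusoid
    pinned to +1 at ED and -1 at ES.  Frames outside the labeled span carry
    ``mask=False``; their value is 0 by default, or the continuation of the
    nearest segment's sinusoid when ``extrapolate`` is set (useful when the
    curve feeds peak detection, where flat zero tails would register as
    spurious plateau extrema).
    """
    labels = validate_labels(labels)
    if len(labels) < 2:
        raise ValidationError("need at least 2 keyframes to construct a curve")
    if n_frames <= labels[-1].frame_index:
        raise ValidationError(
            f"n_frames={n_frames} must exceed the last keyframe index "
            f"{labels[-1].frame_index}"
        )

    values = np.zeros(n_frames, dtype=float)
    mask = np.zeros(n_frames, dtype=bool)
    for f1, f2 in zip(labels, labels[1:]):
        x = np.arange(f1.frame_index, f2.frame_index + 1, dtype=float)
        seg = _segment_value(x, f1, f2)
        values[f1.frame_index : f2.frame_index + 1] = seg
        mask[f1.frame_index : f2.frame_index + 1] = True
    if extrapolate:
        first, last = labels[0], labels[-1]
        if first.frame_index > 0:
            x = np.arange(0, first.frame_index, dtype=float)
            values[: first.frame_index] = np.clip(
                _segment_value(x, labels[0], labels[1]), -1.0, 1.0
            )
        if last.frame_index < n_frames - 1:
            x = np.arange(last.frame_index + 1, n_frames, dtype=float)
            values[last.frame_index + 1 :] = np.clip(
                _segment_value(x, labels[-2], labels[-1]), -1.0, 1.0
            )
    # pin endpoints exactly against floating-point drift
    for kf in labels:
        values[kf.frame_index] = 1.0 if kf.phase is Phase.ED else -1.0
    return PhaseCurve(values=values, mask=mask)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    smoothed = np.convolve(padded, kernel, mode="valid")
    return smoothed[: x.shape[0]]


def _local_extrema(
    y: np.ndarray, mask: np.ndarray, min_separation: int, min_prominence: float, sign: int
):
    """Indices of local maxima of sign*y, left-most supervised frame on plateaus.

    The curve is padded by one below-minimum sample on each side so extrema
    sitting on the first or last frame (common for ground-truth curves) are
    detectable with their full prominence.  An extremum whose plateau touches
    the first or last frame is ambiguous (the true turning point may lie just
    outside the video); it is kept only when its height is within 0.3% of
    the curve range of the global extremum, so exact edge keyframes survive
    but mid-swing cuts do not.  Extrema lying entirely on unsupervised frames
    (mask False) are dropped.
    """
    from scipy.signal import find_peaks

    z = sign * y
    n = z.shape[0]
    if n >= 2:
        z = np.pad(z, 1, mode="constant", constant_values=z.min() - 1.0)
        shift = 1
    else:
        shift = 0
    # plateau_size activates left/right_edges bookkeeping for plateau extrema
    peaks, props = find_peaks(
        z, distance=max(1, min_separation), prominence=min_prominence, plateau_size=1
    )
    left = props.get("left_edges", peaks)
    right = props.get("right_edges", peaks)
    rng_y = float(y.max() - y.min()) if n else 0.0
    zmax = float(z.max()) if n else 0.0
    out = []
    for i, p in enumerate(peaks):
        lo = max(int(left[i]) - shift, 0)
        hi = min(int(right[i]) - shift, n - 1)
        if int(left[i]) - shift <= 0 or int(right[i]) - shift >= n - 1:
            # plateau touches a video boundary
            deficit = zmax - float(z[p])
            if rng_y <= 0 or deficit > 0.003 * rng_y:
                continue
        supervised = [j for j in range(lo, hi + 1) if mask[j]]
        if not supervised:
            continue
        out.append((supervised[0], float(props["prominences"][i])))
    return out


def extract_keyframes(
    curve: PhaseCurve | np.ndarray,
    min_separation: int = 5,
    min_prominence: float = 0.3,
    smooth_window: int = 3,
) -> list[KeyframeLabel]:
    """Invert a (predicted) volume curve into alternating ED/ES keyframes.

    Local maxima become ED, local minima ES, after moving-average smoothing.
    Of any adjacent same-phase pair the lesser-prominence extremum is dropped
    so the output alternates.  Extrema at unsupervised frames (curve mask
    False) are ignored.
    """
    if isinstance(curve, PhaseCurve):
        y, mask = curve.values, curve.mask
    else:
        y = np.asarray(curve, dtype=float)
        mask = np.ones(y.shape, dtype=bool)
    if y.size == 0:
        raise ValidationError("curve must be non-empty")
    if min_separation < 1:
        raise ValidationError("min_separation must be >= 1")
    ys = _moving_average(y, smooth_window)

    cands: list[tuple[int, Phase, float]] = []
    for idx, prom in _local_extrema(ys, mask, min_separation, min_prominence, sign=+1):
        cands.append((idx, Phase.ED, prom))
    for idx, prom in _local_extrema(ys, mask, min_separation, min_prominence, sign=-1):
        cands.append((idx, Phase.ES, prom))
    cands.sort(key=lambda c: c[0])

    # enforce alternation: within any run of equal phases keep the most
    # prominent candidate (ties -> earliest frame)
    out: list[tuple[int, Phase, float]] = []
    for cand in cands:
        if out and out[-1][1] == cand[1]:
            if cand[2] > out[-1][2]:
                out[-1] = cand
        else:
            out.append(cand)
    return [KeyframeLabel(idx, phase) for idx, phase, _ in out]


def find_complete_cycles(labels: Sequence[KeyframeLabel]) -> list[CardiacCycle]:
    """Every consecutive alternating triple (stride 1) is one complete cycle."""
    labels = validate_labels(labels)
    return [
        CardiacCycle(start=a, mid=b, end=c)
        for a, b, c in zip(labels, labels[1:], labels[2:])
    ]


def select_qc_targets(cycle: CardiacCycle) -> QCTargets:
    """Pick the ED and ES frames of a cycle on which QC is run.

    The mid keyframe always participates; the other target is the cycle's
    start keyframe (the earlier of the two same-phase endpoints).
    """
    if cycle.pattern is CyclePattern.ED_ES_ED:
        return QCTargets(ed_frame=cycle.start.frame_index, es_frame=cycle.mid.frame_index, cycle=cycle)
    return QCTargets(ed_frame=cycle.mid.frame_index, es_frame=cycle.start.frame_index, cycle=cycle)


# ---------------------------------------------------------------------------
# JSON interchange: {"video_id", "n_frames", "keyframes": [{"frame", "phase"}]}
# Frame indices are 0-based.


def labels_to_json(video_id: str, n_frames: int, labels: Iterable[KeyframeLabel]) -> str:
    doc = {
        "video_id": video_id,
        "n_frames": int(n_frames),
        "keyframes": [
            {"frame": kf.frame_index, "phase": kf.phase.value} for kf in labels
        ],
    }
    return json.dumps(doc, indent=1)


def labels_from_json(text: str) -> tuple[str, int, list[KeyframeLabel]]:
    doc = json.loads(text)
    labels = validate_labels(
        [KeyframeLabel(int(k["frame"]), Phase(k["phase"])) for k in doc["keyframes"]]
    )
    return str(doc["video_id"]), int(doc["n_frames"]), labels
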