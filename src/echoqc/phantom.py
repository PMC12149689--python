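"""Synthetic apical-four-chamber phantom videos with exhaustive ground truth.

The phantom is *not* a realistic ultrasound simulator — it reproduces the
statistical and geometric structure the QC pipeline consumes: a fan-shaped
sector, seven heart structures as filled oriented ellipses/bars, periodic
left-ventricular contraction whose normalized area follows the ground-truth
volume curve, three gain regimes, a controllable heart-to-image height ratio
and cardiac-axis rotation, structure dropout, and multiplicative speckle.

Every generated video carries the exact labels it induces (keyframes, boxes,
gain class, depth ratio, axis angle) plus the scorecard those labels imply,
computed through the scoring module itself so the two can never diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io import Video
from .lvvc import (
    KeyframeLabel,
    Phase,
    PhaseCurve,
    find_complete_cycles,
    select_qc_targets,
)
from .obb import Detection, OrientedBox, StructureLabel, check_structures
from .quantify import caa_angle, depth_ratio
from .scoring import ScoreCard, score_cycle

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomSample",
    "generate_video",
    "generate_dataset",
    "write_dataset",
    "SCENARIOS",
]


# Canonical heart layout, unit coordinates, y down, apex toward -y.
# (cx, cy, semi_long, semi_short, theta_deg, intensity, shape, area_amp)
# area_amp scales the structure's area with the volume curve.
_LAYOUT = {
    StructureLabel.LV: (-0.19, -0.20, 0.300, 0.150, 90.0, 0.10, "ellipse", 0.35),
    StructureLabel.RV: (0.225, -0.22, 0.260, 0.135, 90.0, 0.16, "ellipse", 0.15),
    StructureLabel.LA: (-0.17, 0.30, 0.180, 0.140, 90.0, 0.13, "ellipse", 0.0),
    StructureLabel.RA: (0.19, 0.30, 0.170, 0.130, 90.0, 0.19, "ellipse", 0.0),
    StructureLabel.IVS: (0.015, -0.20, 0.310, 0.045, 90.0, 0.75, "rect", 0.0),
    StructureLabel.MV: (-0.18, 0.085, 0.130, 0.030, 0.0, 0.85, "rect", 0.0),
    StructureLabel.TV: (0.20, 0.065, 0.120, 0.030, 0.0, 0.85, "rect", 0.0),
}

_SECTOR_INTENSITY = 0.45
GainLevel = Literal["low", "medium", "high"]


@dataclass(frozen=True)
class PhantomSpec:
    n_frames: int = 70
    cycle_length: int = 40  # frames per cardiac cycle; even
    phase_offset: int = 0  # frame index of the first ES
    image_size: int = 128
    depth: float = 0.62  # target heart-to-image height ratio at ES
    axis_deg: float = 85.0  # target LV major-axis angle
    gain: GainLevel = "medium"
    dropout: tuple = ()  # StructureLabel names omitted from render + GT
    speckle_sigma: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_length < 8 or self.cycle_length % 2:
            raise ValueError("cycle_length must be an even integer >= 8")
        if not (0.1 < self.depth < 0.95):
            raise ValueError("depth must lie in (0.1, 0.95)")
        if not (0.0 <= self.axis_deg < 180.0):
            raise ValueError("axis_deg must lie in [0, 180)")
        if self.n_frames < 1 or self.phase_offset < 0:
            raise ValueError("need n_frames >= 1 and phase_offset >= 0")
        object.__setattr__(
            self, "dropout", tuple(StructureLabel(d).value for d in self.dropout)
        )


@dataclass
class PhantomGroundTruth:
    keyframes: list  # of KeyframeLabel
    boxes_per_frame: dict  # frame -> list[Detection] (confidence 1.0)
    gain_class: GainLevel
    depth_ratio: float | None
    caa_deg: float | None
    expected_scorecard: ScoreCard
    phase_curve: PhaseCurve
    video_id: str = ""


@dataclass(frozen=True)
class PhantomSample:
    """A spec plus its scenario tag; pixels are rendered on demand."""

    spec: PhantomSpec
    scenario: str

    def build(self) -> tuple[Video, PhantomGroundTruth]:
        return generate_video(self.spec)


def _volume_curve(spec: PhantomSpec) -> np.ndarray:
    t = np.arange(spec.n_frames, dtype=float)
    return -np.cos(2.0 * np.pi * (t - spec.phase_offset) / spec.cycle_length)


def _keyframes(spec: PhantomSpec) -> list[KeyframeLabel]:
    half = spec.cycle_length // 2
    labels = []
    f, k = spec.phase_offset, 0
    while f < spec.n_frames:
        labels.append(KeyframeLabel(f, Phase.ES if k % 2 == 0 else Phase.ED))
        f, k = f + half, k + 1
    return labels


def _rot(delta_deg: float) -> np.ndarray:
    d = np.deg2rad(delta_deg)
    return np.array([[np.cos(d), -np.sin(d)], [np.sin(d), np.cos(d)]])


def _structures_at(spec: PhantomSpec, y: float) -> dict[StructureLabel, tuple]:
    """Structure geometry in heart units at volume-curve value ``y``.

    Returns label -> (center(2,), a, b, theta_deg) after axis rotation.
    """
    delta = spec.axis_deg - 90.0
    rot = _rot(delta)
    out = {}
    for label, (cx, cy, a, b, th, _inten, _shape, amp) in _LAYOUT.items():
        if label.value in spec.dropout:
            continue
        s = np.sqrt(max(1.0 + amp * y, 0.05))
        center = rot @ np.array([cx, cy])
        out[label] = (center, a * s, b * s, (th + delta) % 180.0)
    return out


def _box_corners_units(center, a, b, theta) -> np.ndarray:
    t = np.deg2rad(theta)
    u = np.array([np.cos(t), np.sin(t)])
    v = np.array([-np.sin(t), np.cos(t)])
    return np.array(
        [center + su * a * u + sv * b * v for su in (-1, 1) for sv in (-1, 1)]
    )


def _calibrate(spec: PhantomSpec) -> tuple[float, np.ndarray]:
    """Scale (units -> px) and pixel offset so the ES-frame union of GT boxes
    spans exactly ``depth * image_size`` vertically, centered in the image."""
    structs = _structures_at(spec, y=-1.0)
    if not structs:
        raise ValueError("cannot calibrate: all structures dropped out")
    corners = np.concatenate(
        [_box_corners_units(c, a, b, th) for c, a, b, th in structs.values()]
    )
    extent = corners[:, 1].max() - corners[:, 1].min()
    scale = spec.depth * spec.image_size / extent
    mid_units = (corners.max(axis=0) + corners.min(axis=0)) / 2.0
    target_px = np.array([spec.image_size / 2.0, spec.image_size * 0.52])
    offset = target_px - scale * mid_units
    return scale, offset


def _gt_boxes(spec: PhantomSpec, y: float, scale: float, offset: np.ndarray) -> list[Detection]:
    dets = []
    for label, (center, a, b, th) in _structures_at(spec, y).items():
        cpx = offset + scale * center
        w, h = 2 * a * scale, 2 * b * scale
        if h > w:
            w, h, th = h, w, (th + 90.0) % 180.0
        dets.append(
            Detection(box=OrientedBox(cpx[0], cpx[1], w, h, th), label=label, confidence=1.0)
        )
    return dets


def _sector_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ax, ay = size / 2.0, 0.02 * size
    dx, dy = xx - ax, yy - ay
    r = np.hypot(dx, dy)
    ang = np.abs(np.arctan2(dx, dy))  # angle off the downward axis
    return (r <= 0.96 * size) & (dy >= 0) & (ang <= np.deg2rad(40.0))


def _render_frame(
    spec: PhantomSpec,
    y: float,
    scale: float,
    offset: np.ndarray,
    sector: np.ndarray,
    grids: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    xx, yy = grids
    img = np.where(sector, _SECTOR_INTENSITY, 0.0)
    for label, (center, a, b, th) in _structures_at(spec, y).items():
        inten = _LAYOUT[label][5]
        shape = _LAYOUT[label][6]
        cpx = offset + scale * center
        apx, bpx = a * scale, b * scale
        t = np.deg2rad(th)
        u = (xx - cpx[0]) * np.cos(t) + (yy - cpx[1]) * np.sin(t)
        v = -(xx - cpx[0]) * np.sin(t) + (yy - cpx[1]) * np.cos(t)
        if shape == "ellipse":
            mask = (u / apx) ** 2 + (v / bpx) ** 2 <= 1.0
        else:
            mask = (np.abs(u) <= apx) & (np.abs(v) <= bpx)
        img[mask] = inten
    return img


def _apply_gain(img: np.ndarray, gain: GainLevel, rng: np.random.Generator) -> np.ndarray:
    if gain == "low":
        return img * 0.4
    if gain == "high":
        out = np.clip(img * 1.8, 0.0, 1.0)
        return np.clip(out + rng.normal(0.0, 0.05, img.shape), 0.0, 1.0)
    return img


def _apply_speckle(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return np.clip(img, 0.0, 1.0)
    # Rayleigh noise normalized to unit mean: first-order ultrasound texture
    noise = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=img.shape)
    return np.clip(img * (1.0 + sigma * (noise - 1.0)), 0.0, 1.0)


def _expected_scorecard(
    spec: PhantomSpec,
    labels: Sequence[KeyframeLabel],
    boxes_per_frame: dict,
) -> ScoreCard:
    """The scorecard the ground truth implies, via the scoring module itself."""
    cycles = find_complete_cycles(labels)
    if not cycles:
        return score_cycle(False, None, None, None, None)
    targets = select_qc_targets(cycles[0])
    dets_ed = boxes_per_frame[targets.ed_frame]
    dets_es = boxes_per_frame[targets.es_frame]
    structure = check_structures(dets_ed, dets_es)
    depth = depth_ratio(dets_es, spec.image_size)
    caa = caa_angle(dets_es)
    return score_cycle(True, spec.gain, structure, depth, caa, cycle=cycles[0])


def generate_video(spec: PhantomSpec) -> tuple[Video, PhantomGroundTruth]:
    """Render one phantom video and its complete ground truth.

    Output is bit-identical for identical specs (the seed is part of the
    spec).
    """
    rng = np.random.default_rng(spec.seed)
    curve = _volume_curve(spec)
    labels = _keyframes(spec)
    scale, offset = _calibrate(spec)
    sector = _sector_mask(spec.image_size)
    yy, xx = np.mgrid[0 : spec.image_size, 0 : spec.image_size].astype(float)
    grids = (xx, yy)

    frames = np.empty((spec.n_frames, spec.image_size, spec.image_size), dtype=np.float32)
    boxes_per_frame: dict[int, list[Detection]] = {}
    for t in range(spec.n_frames):
        img = _render_frame(spec, curve[t], scale, offset, sector, grids)
        img = _apply_gain(img, spec.gain, rng)
        frames[t] = _apply_speckle(img, spec.speckle_sigma, rng)
        boxes_per_frame[t] = _gt_boxes(spec, curve[t], scale, offset)

    video_id = f"phantom-{spec.seed:08d}"
    es_boxes = _gt_boxes(spec, -1.0, scale, offset)
    gt_depth = depth_ratio(es_boxes, spec.image_size)
    gt_caa = caa_angle(es_boxes)
    gt = PhantomGroundTruth(
        keyframes=labels,
        boxes_per_frame=boxes_per_frame,
        gain_class=spec.gain,
        depth_ratio=gt_depth.d,
        caa_deg=gt_caa.c,
        expected_scorecard=_expected_scorecard(spec, labels, boxes_per_frame),
        phase_curve=PhaseCurve(values=curve),
        video_id=video_id,
    )
    return Video(frames=frames, fps=30.0, video_id=video_id), gt


# ---------------------------------------------------------------------------
# Stratified dataset generation

SCENARIOS = (
    "standard",
    "gain_low",
    "gain_high",
    "depth_low",
    "depth_high",
    "caa_low",
    "caa_high",
    "dropout_essential",
    "dropout_valve",
    "incomplete",
)
_ALIASES = {"gain_medium": "standard"}


def _sample_spec(scenario: str, rng: np.random.Generator, image_size: int, seed: int) -> PhantomSpec:
    cycle = 2 * int(rng.integers(12, 21))  # 24..40 frames
    offset = int(rng.integers(0, cycle // 2))
    n_frames = offset + cycle + int(rng.integers(2, cycle // 2))
    spec = PhantomSpec(
        n_frames=n_frames,
        cycle_length=cycle,
        phase_offset=offset,
        image_size=image_size,
        depth=float(rng.uniform(0.56, 0.70)),
        axis_deg=float(rng.uniform(79.0, 91.0)),
        gain="medium",
        dropout=(),
        speckle_sigma=float(rng.uniform(0.08, 0.16)),
        seed=seed,
    )
    if scenario == "standard":
        return spec
    if scenario == "gain_low":
        return replace(spec, gain="low")
    if scenario == "gain_high":
        return replace(spec, gain="high")
    if scenario == "depth_low":
        return replace(spec, depth=float(rng.uniform(0.30, 0.44)))
    if scenario == "depth_high":
        return replace(spec, depth=float(rng.uniform(0.80, 0.92)))
    if scenario == "caa_low":
        return replace(spec, axis_deg=float(rng.uniform(50.0, 70.0)))
    if scenario == "caa_high":
        return replace(spec, axis_deg=float(rng.uniform(100.0, 120.0)))
    if scenario == "dropout_essential":
        victim = ["LV", "RV", "LA", "RA", "IVS"][int(rng.integers(0, 5))]
        return replace(spec, dropout=(victim,))
    if scenario == "dropout_valve":
        victim = (("MV",), ("TV",), ("MV", "TV"))[int(rng.integers(0, 3))]
        return replace(spec, dropout=victim)
    if scenario == "incomplete":
        n = offset + cycle // 2 + int(rng.integers(1, max(2, cycle // 4)))
        return replace(spec, n_frames=n)
    raise ValueError(f"unknown scenario {scenario!r}")


def _allocate(n: int, balance: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of n samples across scenarios."""
    names = [_ALIASES.get(k, k) for k in balance]
    for name in names:
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
    weights = np.array([float(v) for v in balance.values()], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("balance weights must be positive")
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for name, c in zip(names, counts):
        out.extend([name] * int(c))
    return out


def generate_dataset(
    n: int,
    balance: dict[str, float] | None = None,
    seed: int = 0,
    image_size: int = 128,
) -> list[PhantomSample]:
    """Deterministic stratified phantom specs; render each via ``.build()``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if balance is None:
        balance = {s: 1.0 for s in SCENARIOS}
    scenarios = _allocate(n, balance)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    samples = [
        PhantomSample(
            spec=_sample_spec(sc, rng, image_size, int(seeds[i])), scenario=sc
        )
        for i, sc in enumerate(scenarios)
    ]
    order = rng.permutation(n)
    return [samples[i] for i in order]


def write_dataset(samples: Sequence[PhantomSample], out_dir: str | Path) -> Path:
    """Write frames (PNG stacks), annotation JSONs and a manifest CSV."""
    import pandas as pd

    from .io import write_video_frames
    from .lvvc import labels_to_json
    from .obb import detections_to_json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample in enumerate(samples):
        video, gt = sample.build()
        vid = f"{i:04d}_{gt.video_id}"
        vdir = out_dir / vid
        write_video_frames(video, vdir / "frames")
        (vdir / "keyframes.json").write_text(
            labels_to_json(vid, video.n_frames, gt.keyframes)
        )
        (vdir / "boxes.json").write_text(
            detections_to_json(gt.boxes_per_frame, with_conf=False)
        )
        gt.phase_curve.to_csv(vdir / "phase_curve.csv")
        import json

        (vdir / "gain.json").write_text(json.dumps({"gain": gt.gain_class}))
        rows.append(
            {
                "video_id": vid,
                "scenario": sample.scenario,
                "n_frames": video.n_frames,
                "gain": gt.gain_class,
                "depth": round(gt.depth_ratio, 4) if gt.depth_ratio is not None else "",
                "caa_deg": round(gt.caa_deg, 2) if gt.caa_deg is not None else "",
                "expected_total": gt.expected_scorecard.total,
                "seed": sample.spec.seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
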