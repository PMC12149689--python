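"""Staged training on desk-scale data.

Stage 1 trains the detector together with the backbone (dense per-pixel
class + circular-smooth-label angle loss).  Stages 2 and 3 freeze the
backbone — its parameters are never touched again — and fit the recurrent
phase regressor (masked MSE against the ground-truth volume curve on
fixed-length windows guaranteed to contain a labeled triple) and the gain
classifier (cross-entropy on pooled deep features).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..config import RunConfig
from ..lvvc import KeyframeLabel, lvvc_ground_truth
from ..obb import Detection, csl_encode
from .core import CLASS_ORDER, Backbone, DetectorHead, GainHead, ModelBundle, PhaseHead, pooled_features
from .nn import Adam, bce_logits, mse_masked, softmax_ce

__all__ = [
    "DetectorSample",
    "PhaseSample",
    "GainSample",
    "train_detector",
    "train_phase",
    "train_gain",
    "phantom_training_sets",
]

_CLASS_INDEX = {label: i + 1 for i, label in enumerate(CLASS_ORDER)}  # 0 = background


@dataclass
class DetectorSample:
    frame: np.ndarray  # (H, W) in [0, 1]
    boxes: list  # of Detection (ground truth)


@dataclass
class PhaseSample:
    frames: np.ndarray  # (T, H, W)
    labels: list  # of KeyframeLabel


@dataclass
class GainSample:
    frame: np.ndarray
    gain: str  # low | medium | high


def _rasterize_targets(boxes: Sequence[Detection], h2: int, w2: int, stride: int,
                       n_bins: int, csl_radius: int):
    """Per-pixel class-index map and CSL angle targets at feature resolution.

    Larger boxes are drawn first so thin bars (septum, valves) survive
    overlap.  Also returns each pixel's owning angle bin (-1 on background)
    for frequency balancing of the angle loss.
    """
    cls_map = np.zeros((h2, w2), dtype=np.int64)
    ang_target = np.zeros((n_bins, h2, w2), dtype=np.float32)
    fg = np.zeros((h2, w2), dtype=np.float32)
    ang_bin = np.full((h2, w2), -1, dtype=np.int64)
    jj, ii = np.meshgrid(np.arange(w2), np.arange(h2))
    xs = stride * jj + (stride - 1) / 2.0
    ys = stride * ii + (stride - 1) / 2.0
    for det in sorted(boxes, key=lambda d: -d.box.area):
        b = det.box
        t = np.deg2rad(b.theta)
        u = (xs - b.cx) * np.cos(t) + (ys - b.cy) * np.sin(t)
        v = -(xs - b.cx) * np.sin(t) + (ys - b.cy) * np.cos(t)
        mask = (np.abs(u) <= b.w / 2) & (np.abs(v) <= b.h / 2)
        if not mask.any():
            continue
        cls_map[mask] = _CLASS_INDEX[det.label]
        ang_target[:, mask] = csl_encode(b.theta, csl_radius, n_bins)[:, None]
        fg[mask] = 1.0
        ang_bin[mask] = int(round(b.theta * n_bins / 180.0)) % n_bins
    return cls_map, ang_target, fg, ang_bin


def train_detector(dataset: Sequence[DetectorSample], config: RunConfig) -> ModelBundle:
    """Stage 1: jointly train backbone + detection head."""
    if not dataset:
        raise ValueError("detector dataset is empty")
    mc = config.model
    rng = np.random.default_rng(config.seed)
    backbone = Backbone(mc.backbone_channels, rng)
    detector = DetectorHead(backbone.out_channels, config.detection.csl_bins, rng)
    base_lr = 2.0 * mc.learning_rate
    opt = Adam(backbone.params() + detector.params(), lr=base_lr)
    stride = backbone.stride
    radius = config.detection.csl_window_radius

    targets = []
    for s in dataset:
        h2, w2 = s.frame.shape[0] // stride, s.frame.shape[1] // stride
        cls_map, ang_target, fg, ang_bin = _rasterize_targets(
            s.boxes, h2, w2, stride, detector.n_bins, radius
        )
        # sqrt-class-balanced pixel weights: lift thin bars (septum, valves)
        # without drowning the background, whose accuracy bounds box extents
        counts = np.bincount(cls_map.reshape(-1), minlength=detector.n_classes)
        w_class = np.sqrt(
            np.where(counts > 0, cls_map.size / (detector.n_classes * np.maximum(counts, 1)), 0.0)
        )
        # never down-weight background below 1: a weak background penalty
        # lets the head hallucinate structures from the position prior alone
        w_class[0] = max(w_class[0], 1.0)
        weights = w_class[cls_map].astype(np.float32)
        targets.append((cls_map, ang_target, fg, weights, ang_bin))

    # angle-frequency balancing: without it the head collapses onto the
    # dataset's modal orientation and rotated hearts get the wrong angle
    bin_hist = np.zeros(detector.n_bins, dtype=np.int64)
    for _cls, _at, _fg, _w, ang_bin in targets:
        sel = ang_bin[ang_bin >= 0]
        bin_hist += np.bincount(sel, minlength=detector.n_bins)
    nonzero = bin_hist[bin_hist > 0]
    ref = float(np.median(nonzero)) if nonzero.size else 1.0
    bin_w = np.ones(detector.n_bins, dtype=np.float32)
    pos = bin_hist > 0
    bin_w[pos] = np.clip(np.sqrt(ref / bin_hist[pos]), 0.25, 8.0)

    trace: list[float] = []
    for epoch in range(mc.detector_epochs):
        # cosine learning-rate decay
        opt.lr = base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / mc.detector_epochs))
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for idx in order:
            s = dataset[idx]
            cls_map, ang_target, fg, weights, ang_bin = targets[idx]
            opt.zero_grad()
            feats = backbone.forward(s.frame[None])
            cls_logits, ang_logits = detector.forward(feats)
            cls_loss, dcls = softmax_ce(
                cls_logits[0].transpose(1, 2, 0), cls_map, weights=weights
            )
            ang_pixel_w = fg * bin_w[np.clip(ang_bin, 0, detector.n_bins - 1)]
            ang_loss, dang = bce_logits(
                ang_logits[0], ang_target,
                mask=np.broadcast_to(ang_pixel_w, ang_logits[0].shape),
            )
            dfeat = detector.backward(
                dcls.transpose(2, 0, 1)[None], (5.0 * dang)[None]
            )
            backbone.backward(dfeat)
            opt.step()
            epoch_loss += cls_loss + 5.0 * ang_loss
        trace.append(epoch_loss / len(dataset))

    bundle = ModelBundle(backbone=backbone, detector=detector,
                         config_echo={"seed": config.seed})
    bundle.history = {"detector_loss": trace}
    return bundle


def _video_features(backbone: Backbone, frames: np.ndarray, chunk: int = 16) -> np.ndarray:
    """Frozen-backbone pooled features for every frame: (T, C)."""
    feats = [
        pooled_features(backbone.forward(frames[i : i + chunk]))
        for i in range(0, frames.shape[0], chunk)
    ]
    return np.concatenate(feats, axis=0)


def _sample_window(
    labels: Sequence[KeyframeLabel], n_frames: int, seg_len: int, rng: np.random.Generator
) -> tuple[int, int]:
    """A [start, start+seg_len) window guaranteed to contain a labeled triple
    (when one exists); returns (start, pad) where pad is trailing edge padding."""
    if n_frames <= seg_len:
        return 0, seg_len - n_frames
    if len(labels) >= 3:
        n_triples = len(labels) - 2
        r = int(rng.integers(0, n_triples))
        first, last = labels[r].frame_index, labels[r + 2].frame_index
        lo = max(0, last - seg_len + 1)
        hi = min(first, n_frames - seg_len)
        if hi < lo:  # triple longer than the window: anchor at its start
            start = max(0, min(first, n_frames - seg_len))
        else:
            start = int(rng.integers(lo, hi + 1))
        assert any(
            start <= labels[i].frame_index and labels[i + 2].frame_index < start + seg_len
            for i in range(n_triples)
        ) or last - first >= seg_len, "sampled window must contain a labeled triple"
        return start, 0
    return int(rng.integers(0, n_frames - seg_len + 1)), 0


def train_phase(
    dataset: Sequence[PhaseSample], bundle: ModelBundle, config: RunConfig
) -> ModelBundle:
    """Stage 2: freeze the backbone, fit the recurrent volume-curve regressor."""
    if not dataset:
        raise ValueError("phase dataset is empty")
    mc = config.model
    rng = np.random.default_rng(config.seed + 1)
    head = PhaseHead(bundle.backbone.out_channels, mc.rnn_hidden, mc.rnn_layers, rng)
    opt = Adam(head.params(), lr=mc.learning_rate)

    extrapolate = mc.extrapolate_phase_targets
    cached = []
    for s in dataset:
        feats = _video_features(bundle.backbone, s.frames)
        # extrapolated targets supervise the frames outside the labeled span
        # with the periodic continuation; without them the regressor is
        # unconstrained there and its noise bumps register as fake keyframes
        # on videos cut mid-cycle
        curve = lvvc_ground_truth(s.labels, s.frames.shape[0], extrapolate=extrapolate)
        mask = np.ones(len(curve.values), dtype=bool) if extrapolate else curve.mask
        cached.append((feats, curve.values.astype(np.float32), mask))

    trace: list[float] = []
    for _epoch in range(mc.phase_epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for idx in order:
            feats, values, mask = cached[idx]
            start, pad = _sample_window(
                dataset[idx].labels, feats.shape[0], mc.segment_length, rng
            )
            f = feats[start : start + mc.segment_length]
            y = values[start : start + mc.segment_length]
            m = mask[start : start + mc.segment_length].copy()
            if pad:
                f = np.concatenate([f, np.repeat(f[-1:], pad, axis=0)])
                y = np.concatenate([y, np.zeros(pad, dtype=np.float32)])
                m = np.concatenate([m, np.zeros(pad, dtype=bool)])
            opt.zero_grad()
            pred = head.forward(f)
            loss, dpred = mse_masked(pred, y, m)
            head.backward(dpred)
            opt.step()
            epoch_loss += loss
        trace.append(epoch_loss / len(dataset))

    out = ModelBundle(
        backbone=bundle.backbone, detector=bundle.detector,
        phase_head=head, gain_head=bundle.gain_head,
        config_echo=dict(bundle.config_echo),
    )
    out.history = {**getattr(bundle, "history", {}), "phase_loss": trace}
    return out


def train_gain(
    dataset: Sequence[GainSample], bundle: ModelBundle, config: RunConfig
) -> ModelBundle:
    """Stage 3: freeze the backbone, fit the gain classifier on deep features."""
    if not dataset:
        raise ValueError("gain dataset is empty")
    levels = GainHead.LEVELS
    present = {s.gain for s in dataset}
    missing = set(levels) - present
    if missing:
        raise ValueError(f"gain classes absent from training data: {sorted(missing)}")
    mc = config.model
    rng = np.random.default_rng(config.seed + 2)
    head = GainHead(bundle.backbone.out_channels, rng=rng)
    opt = Adam(head.params(), lr=10 * mc.learning_rate)

    frames = np.stack([s.frame for s in dataset])
    feats = np.concatenate(
        [pooled_features(bundle.backbone.forward(frames[i : i + 16]))
         for i in range(0, frames.shape[0], 16)]
    )
    labels = np.array([levels.index(s.gain) for s in dataset])

    trace: list[float] = []
    n = len(dataset)
    bs = max(8, config.model.batch_size)
    for _epoch in range(mc.gain_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, bs):
            sel = order[i : i + bs]
            opt.zero_grad()
            logits = head.forward(feats[sel])
            loss, dlogits = softmax_ce(logits, labels[sel])
            head.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
        trace.append(epoch_loss / n)

    out = ModelBundle(
        backbone=bundle.backbone, detector=bundle.detector,
        phase_head=bundle.phase_head, gain_head=head,
        config_echo=dict(bundle.config_echo),
    )
    out.history = {**getattr(bundle, "history", {}), "gain_loss": trace}
    return out


def phantom_training_sets(
    samples, frames_per_video: int = 2, seed: int = 0
) -> tuple[list[DetectorSample], list[PhaseSample], list[GainSample]]:
    """Render phantom samples into the three task datasets.

    Incomplete-cycle phantoms are excluded from the phase set (fewer than two
    keyframes cannot anchor a ground-truth curve).
    """
    rng = np.random.default_rng(seed)
    det: list[DetectorSample] = []
    phase: list[PhaseSample] = []
    gain: list[GainSample] = []
    for sample in samples:
        video, gt = sample.build()
        picks = rng.choice(video.n_frames, size=min(frames_per_video, video.n_frames),
                           replace=False)
        for t in picks:
            det.append(DetectorSample(frame=video.frames[t], boxes=gt.boxes_per_frame[int(t)]))
            gain.append(GainSample(frame=video.frames[t], gain=gt.gain_class))
        if len(gt.keyframes) >= 2:
            phase.append(PhaseSample(frames=video.frames, labels=gt.keyframes))
    return det, phase, gain
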