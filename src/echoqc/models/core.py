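"""Model components with fixed contracts.

* :class:`Backbone` — a small convolutional pyramid shared by all heads.
  Frames enter with two normalized coordinate channels appended so per-pixel
  heads can exploit the roughly canonical anatomy layout.
* :class:`DetectorHead` — dense per-pixel structure classification plus a
  circular-smooth-label angle map on the backbone features; connected
  components of the class probability maps are decoded into oriented boxes
  (center from the centroid, extents from principal-axis projections, angle
  from the CSL argmax).
* :class:`PhaseHead` — bidirectional recurrent regressor of the per-frame
  volume proxy from globally pooled, per-video standardized features.
* :class:`GainHead` — softmax classifier over {low, medium, high} on the
  pooled deep features.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ..obb import Detection, OrientedBox, StructureLabel, csl_decode, rotated_nms
from .nn import Adam, BiRNN, Conv2d, Linear, MaxPool2, ReLU, sigmoid, softmax

__all__ = ["Backbone", "DetectorHead", "PhaseHead", "GainHead", "ModelBundle",
           "CLASS_ORDER", "pooled_features"]

#: Detector class channel order; channel 0 is background.
CLASS_ORDER = [
    StructureLabel.LV, StructureLabel.RV, StructureLabel.LA,
    StructureLabel.RA, StructureLabel.IVS, StructureLabel.MV, StructureLabel.TV,
]


def _coord_channels(h: int, w: int) -> np.ndarray:
    ys = np.linspace(-1.0, 1.0, h, dtype=np.float32)
    xs = np.linspace(-1.0, 1.0, w, dtype=np.float32)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return np.stack([xx, yy])


class Backbone:
    """conv3x3 -> pool2 -> conv3x3 -> dilated conv3x3; output stride 2.

    The dilated third convolution widens the receptive field (~30 input
    pixels) without a second pooling step, keeping thin structures several
    feature pixels wide.
    """

    stride = 2

    def __init__(self, channels=(10, 20, 24), rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = channels
        self.channels = (c1, c2, c3)
        self.conv1 = Conv2d(3, c1, 3, rng)
        self.relu1 = ReLU()
        self.pool = MaxPool2()
        self.conv2 = Conv2d(c1, c2, 3, rng)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(c2, c3, 3, rng, dilation=2)
        self.relu3 = ReLU()
        self.out_channels = c3

    def params(self):
        return self.conv1.params() + self.conv2.params() + self.conv3.params()

    def forward(self, frames: np.ndarray) -> np.ndarray:
        """(N, H, W) grayscale in [0,1] -> (N, C, H/2, W/2) features."""
        n, h, w = frames.shape
        coords = np.broadcast_to(_coord_channels(h, w), (n, 2, h, w))
        x = np.concatenate([frames[:, None].astype(np.float32), coords], axis=1)
        x = self.relu1.forward(self.conv1.forward(x))
        x = self.pool.forward(x)
        x = self.relu2.forward(self.conv2.forward(x))
        return self.relu3.forward(self.conv3.forward(x))

    def backward(self, dout: np.ndarray) -> None:
        d = self.relu3.backward(dout)
        d = self.conv3.backward(d)
        d = self.relu2.backward(d)
        d = self.conv2.backward(d)
        d = self.pool.backward(d)
        d = self.relu1.backward(d)
        self.conv1.backward(d)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()


def pooled_features(features: np.ndarray) -> np.ndarray:
    """Global average pooling: (N, C, H, W) -> (N, C)."""
    return features.mean(axis=(2, 3))


def _refine_angle(xs: np.ndarray, ys: np.ndarray, pw: np.ndarray, theta: float) -> float:
    """Principal-axis angle for clearly elongated regions, CSL otherwise.

    At this backbone's receptive field the per-pixel CSL map cannot observe
    the global orientation of a chamber-sized region, so the region's second
    moments are the more reliable estimator whenever the shape itself pins
    the axis down (eigenvalue ratio >= 2); near-isotropic regions keep the
    CSL angle.
    """
    mx, my = np.average(xs, weights=pw), np.average(ys, weights=pw)
    cxx = np.average((xs - mx) ** 2, weights=pw)
    cyy = np.average((ys - my) ** 2, weights=pw)
    cxy = np.average((xs - mx) * (ys - my), weights=pw)
    lam = np.sqrt(max((cxx - cyy) ** 2 / 4.0 + cxy**2, 0.0))
    l1 = (cxx + cyy) / 2.0 + lam
    l2 = (cxx + cyy) / 2.0 - lam
    if l2 <= 0 or l1 / max(l2, 1e-9) < 2.0:
        return theta  # near-isotropic region: moments are noise
    return float(np.degrees(0.5 * np.arctan2(2.0 * cxy, cxx - cyy)) % 180.0)


def _weighted_span(coords: np.ndarray, weights: np.ndarray, q: float = 0.01) -> float:
    """Span between the q and 1-q weighted quantiles of ``coords``."""
    order = np.argsort(coords)
    c, w = coords[order], weights[order]
    cum = np.cumsum(w)
    cum = cum / cum[-1]
    lo = c[np.searchsorted(cum, q)]
    hi = c[min(np.searchsorted(cum, 1.0 - q), c.size - 1)]
    return float(hi - lo)


class DetectorHead:
    def __init__(self, c_in: int, n_bins: int = 180, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_bins = n_bins
        self.n_classes = len(CLASS_ORDER) + 1  # + background
        self.cls_conv = Conv2d(c_in, self.n_classes, 1, rng)
        self.ang_conv = Conv2d(c_in, n_bins, 1, rng)

    def params(self):
        return self.cls_conv.params() + self.ang_conv.params()

    def forward(self, features: np.ndarray):
        return self.cls_conv.forward(features), self.ang_conv.forward(features)

    def backward(self, dcls: np.ndarray, dang: np.ndarray) -> np.ndarray:
        return self.cls_conv.backward(dcls) + self.ang_conv.backward(dang)

    def decode(
        self,
        cls_logits: np.ndarray,
        ang_logits: np.ndarray,
        stride: int = 2,
        prob_thresh: float = 0.7,
        min_area: int = 4,
        nms_iou: float = 0.5,
    ) -> list[Detection]:
        """Decode one frame's dense maps into NMS-filtered detections.

        Connected components of each class probability map become candidate
        boxes: the center is the probability-weighted centroid, extents are
        debiased weighted quantile spans along the box axes, and the angle is
        the CSL argmax over region-pooled scores — replaced by the region's
        principal axis when the region is clearly elongated (see
        :func:`_refine_angle`).
        """
        probs = softmax(cls_logits.transpose(1, 2, 0))  # (H, W, n_classes)
        ang_scores = sigmoid(ang_logits)  # (bins, H, W)
        dets: list[Detection] = []
        for ci, label in enumerate(CLASS_ORDER, start=1):
            pmap = probs[:, :, ci]
            mask = pmap > prob_thresh
            if not mask.any():
                continue
            comp, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
            for comp_id in range(1, n_comp + 1):
                sel = comp == comp_id
                if sel.sum() < min_area:
                    continue
                conf = float(np.clip(pmap[sel].mean(), 0.0, 1.0))
                pw = pmap[sel] ** 4  # sharpen: de-weight boundary bleed
                theta = csl_decode((ang_scores[:, sel] * pw).sum(axis=1))
                ii, jj = np.nonzero(sel)
                # feature pixel (i, j) covers image pixels centered at
                # stride*j + (stride-1)/2
                xs = stride * jj + (stride - 1) / 2.0
                ys = stride * ii + (stride - 1) / 2.0
                theta = _refine_angle(xs, ys, pw, theta)
                t = np.deg2rad(theta)
                u = xs * np.cos(t) + ys * np.sin(t)
                v = -xs * np.sin(t) + ys * np.cos(t)
                # quantile spans under-estimate the true extent; divide by the
                # uniform-density expectation (1 - 2q) to debias
                q = 0.02
                w = _weighted_span(u, pw, q) / (1 - 2 * q) + 0.5 * stride
                h = _weighted_span(v, pw, q) / (1 - 2 * q) + 0.5 * stride
                if h > w:
                    w, h, theta = h, w, (theta + 90.0) % 180.0
                cx = float(np.average(xs, weights=pw))
                cy = float(np.average(ys, weights=pw))
                dets.append(
                    Detection(
                        box=OrientedBox(cx, cy, max(w, 1.0), max(min(h, w), 1.0), theta),
                        label=label,
                        confidence=conf,
                    )
                )
        return rotated_nms(dets, iou_thresh=nms_iou)


class PhaseHead:
    """Per-video standardized pooled features -> BiRNN -> scalar per frame."""

    def __init__(self, d_in: int, hidden: int = 24, n_layers: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.rnn = BiRNN(d_in, hidden, n_layers, rng)
        self.out = Linear(2 * hidden, 1, rng)

    def params(self):
        return self.rnn.params() + self.out.params()

    @staticmethod
    def standardize(feats: np.ndarray) -> np.ndarray:
        """z-score each channel over time: removes static gain/layout offsets."""
        mu = feats.mean(axis=0, keepdims=True)
        sd = feats.std(axis=0, keepdims=True)
        return ((feats - mu) / (sd + 1e-6)).astype(np.float32)

    def forward(self, feats: np.ndarray) -> np.ndarray:
        """(T, C) pooled features -> (T,) raw curve values (unclipped)."""
        h = self.rnn.forward(self.standardize(feats))
        self._h = h
        return self.out.forward(h)[:, 0]

    def backward(self, dcurve: np.ndarray) -> None:
        d = self.out.backward(dcurve[:, None])
        self.rnn.backward(d)

    def predict(self, feats: np.ndarray) -> np.ndarray:
        # a video with no temporal feature variation carries no phase signal;
        # short-circuit to a flat curve rather than emit the recurrence's
        # initial-state transient
        if float(feats.std(axis=0).max()) < 1e-5:
            return np.zeros(feats.shape[0], dtype=np.float32)
        return np.clip(self.forward(feats), -1.0, 1.0)


class GainHead:
    """Pooled deep features -> two fully connected layers -> 3 gain levels.

    The hidden layer lets the head discount heart-size effects (a small dark
    heart lowers the global mean the same way low gain does).
    """

    LEVELS = ("low", "medium", "high")

    def __init__(self, d_in: int, hidden: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(d_in, hidden, rng)
        self.act = ReLU()
        self.fc2 = Linear(hidden, 3, rng)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, feats: np.ndarray) -> np.ndarray:
        h = self.act.forward(self.fc1.forward(feats.astype(np.float32)))
        return self.fc2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        self.fc1.backward(self.act.backward(self.fc2.backward(dlogits)))

    def predict_proba(self, feats: np.ndarray) -> np.ndarray:
        return softmax(self.forward(feats))

    def predict(self, feats: np.ndarray) -> list[str]:
        return [self.LEVELS[i] for i in self.predict_proba(feats).argmax(axis=1)]


@dataclass
class ModelBundle:
    """Shared backbone plus the trained task heads."""

    backbone: Backbone
    detector: DetectorHead | None = None
    phase_head: PhaseHead | None = None
    gain_head: GainHead | None = None
    config_echo: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)  # training loss traces

    # -- persistence ------------------------------------------------------
    def _named_params(self) -> dict[str, np.ndarray]:
        out = {}
        groups = {
            "backbone": self.backbone.params(),
            "detector": self.detector.params() if self.detector else [],
            "phase": self.phase_head.params() if self.phase_head else [],
            "gain": self.gain_head.params() if self.gain_head else [],
        }
        for group, params in groups.items():
            for i, p in enumerate(params):
                out[f"{group}.{i}"] = p.value
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = dict(self.config_echo)
        meta["_heads"] = {
            "detector": self.detector is not None,
            "phase": self.phase_head is not None,
            "gain": self.gain_head is not None,
        }
        meta["_arch"] = {
            "channels": list(self.backbone.channels),
            "n_bins": self.detector.n_bins if self.detector else 180,
            "rnn_hidden": (
                self.phase_head.rnn.layers[0][0].b.value.shape[0] if self.phase_head else 24
            ),
            "rnn_layers": len(self.phase_head.rnn.layers) if self.phase_head else 2,
        }
        np.savez(path, _meta=json.dumps(meta), **self._named_params())

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        arch, heads = meta["_arch"], meta["_heads"]
        rng = np.random.default_rng(0)
        backbone = Backbone(tuple(arch["channels"]), rng)
        c2 = backbone.out_channels
        bundle = cls(
            backbone=backbone,
            detector=DetectorHead(c2, arch["n_bins"], rng) if heads["detector"] else None,
            phase_head=(
                PhaseHead(c2, arch["rnn_hidden"], arch["rnn_layers"], rng)
                if heads["phase"] else None
            ),
            gain_head=GainHead(c2, rng=rng) if heads["gain"] else None,
            config_echo={k: v for k, v in meta.items() if not k.startswith("_")},
        )
        for key, params in (
            ("backbone", bundle.backbone.params()),
            ("detector", bundle.detector.params() if bundle.detector else []),
            ("phase", bundle.phase_head.params() if bundle.phase_head else []),
            ("gain", bundle.gain_head.params() if bundle.gain_head else []),
        ):
            for i, p in enumerate(params):
                p.value = data[f"{key}.{i}"].astype(np.float32)
        return bundle
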