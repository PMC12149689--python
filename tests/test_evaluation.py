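import itertools
import warnings

import numpy as np
import pytest

from echoqc.evaluation import (
    classification_report,
    cohens_kappa,
    detection_map,
    frame_error,
    frame_error_stats,
)
from echoqc.lvvc import KeyframeLabel, Phase
from echoqc.obb import Detection, OrientedBox, StructureLabel

ED, ES = Phase.ED, Phase.ES


def kf(frame, phase):
    return KeyframeLabel(frame, phase)


def det(label, cx, conf=1.0, w=20.0, h=10.0, theta=0.0):
    return Detection(box=OrientedBox(cx, 50.0, w, h, theta), label=label,
                     confidence=conf)


# ---------------------------------------------------------------------------
# frame error


class TestFrameError:
    def test_identical_zero(self):
        labels = [kf(0, ED), kf(10, ES), kf(20, ED)]
        e = frame_error(labels, labels)
        assert e[ED] == [0, 0] and e[ES] == [0] and e["misses"] == 0

    def test_offset_two(self):
        e = frame_error([kf(12, ED)], [kf(10, ED)])
        assert e[ED] == [2]

    def test_miss_counted(self):
        e = frame_error([kf(11, ED)], [kf(10, ED), kf(30, ED)])
        assert e[ED] == [1] and e["misses"] == 1

    def test_phase_respected(self):
        # an ES prediction can never match an ED ground truth
        e = frame_error([kf(10, ES)], [kf(10, ED)])
        assert e[ED] == [] and e["misses"] == 1

    def test_permutation_invariance(self, rng):
        gt = [kf(5, ED), kf(15, ES), kf(25, ED), kf(40, ES)]
        pred = [kf(6, ED), kf(14, ES), kf(27, ED)]
        base = frame_error(pred, gt)
        for _ in range(5):
            p = [pred[i] for i in rng.permutation(len(pred))]
            g = [gt[i] for i in rng.permutation(len(gt))]
            e = frame_error(p, g)
            assert e[ED] == base[ED] and e[ES] == base[ES]
            assert e["misses"] == base["misses"]

    def test_one_to_one_matching(self):
        # two GT EDs cannot share the single closest prediction
        e = frame_error([kf(10, ED)], [kf(9, ED), kf(11, ED)])
        assert sorted(e[ED]) == [1] and e["misses"] == 1

    def test_stats_aggregation(self):
        per_video = [
            frame_error([kf(10, ED), kf(20, ES)], [kf(12, ED), kf(20, ES)]),
            frame_error([kf(5, ED)], [kf(5, ED), kf(30, ES)]),
        ]
        stats = frame_error_stats(per_video)
        assert stats.fe_ed_mean == pytest.approx(1.0)  # errors 2 and 0
        assert stats.fe_es_mean == pytest.approx(0.0)
        assert stats.misses == 1
        assert stats.n_videos == 2


# ---------------------------------------------------------------------------
# detection mAP


class TestDetectionMap:
    def test_perfect(self):
        gts = [[det(StructureLabel.LV, 30), det(StructureLabel.RV, 70)]]
        ev = detection_map(gts, gts)
        assert ev.map == ev.mp == ev.mr == 1.0

    def test_empty_predictions(self):
        gts = [[det(StructureLabel.LV, 30)]]
        ev = detection_map([[]], gts)
        assert ev.map == 0.0 and ev.mr == 0.0

    def test_tp_then_fp(self):
        gt = [det(StructureLabel.LV, 30)]
        preds = [[det(StructureLabel.LV, 30, conf=0.9),
                  det(StructureLabel.LV, 80, conf=0.5)]]
        ev = detection_map(preds, [gt])
        # PR curve: (r=1, p=1) then (r=1, p=0.5) -> all-point AP = 1.0
        assert ev.per_class_ap[StructureLabel.LV] == pytest.approx(1.0)
        # precision at conf >= 0.25 counts both predictions: 1 TP / 2
        assert ev.mp == pytest.approx(0.5)
        assert ev.mr == pytest.approx(1.0)

    def test_map_is_mean_of_per_class(self, rng):
        preds, gts = _random_detection_problem(rng, n_images=4)
        ev = detection_map(preds, gts)
        assert ev.map == pytest.approx(float(np.mean(list(ev.per_class_ap.values()))))

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_ap_oracle(self, seed):
        """AP matches explicit enumeration over all confidence cutoffs on
        instances with <= 5 boxes."""
        rng = np.random.default_rng(seed)
        preds, gts = _random_detection_problem(rng, n_images=2, max_boxes=3)
        ev = detection_map(preds, gts)
        for label, ap in ev.per_class_ap.items():
            assert ap == pytest.approx(_brute_force_ap(preds, gts, label), abs=1e-9)


def _random_detection_problem(rng, n_images=3, max_boxes=3):
    labels = [StructureLabel.LV, StructureLabel.RV]
    preds, gts = [], []
    for _ in range(n_images):
        g, p = [], []
        for label in labels:
            for _ in range(int(rng.integers(0, max_boxes))):
                cx = float(rng.uniform(20, 200))
                g.append(det(label, cx))
                if rng.random() < 0.8:  # jittered prediction
                    p.append(det(label, cx + float(rng.uniform(-3, 3)),
                                 conf=float(rng.uniform(0.3, 1.0))))
        for _ in range(int(rng.integers(0, 2))):  # false positives
            p.append(det(labels[int(rng.integers(0, 2))],
                         float(rng.uniform(300, 400)),
                         conf=float(rng.uniform(0.3, 1.0))))
        preds.append(p)
        gts.append(g)
    return preds, gts


def _brute_force_ap(preds, gts, label, iou_thresh=0.5):
    """Independent AP: recompute the PR curve point by point from scratch,
    matching greedily inside each image by confidence order, then integrate
    the monotone envelope by explicit Riemann summation over recall steps."""
    from echoqc.obb import rotated_iou

    rows = []
    n_gt = 0
    for img, (p_frame, g_frame) in enumerate(zip(preds, gts)):
        g_boxes = [g for g in g_frame if g.label == label]
        n_gt += len(g_boxes)
        taken = set()
        for d in sorted([d for d in p_frame if d.label == label],
                        key=lambda d: -d.confidence):
            best, best_iou = None, iou_thresh
            for gi, g in enumerate(g_boxes):
                if gi in taken:
                    continue
                iou = rotated_iou(d.box, g.box)
                if iou >= best_iou:
                    best, best_iou = gi, iou
            if best is not None:
                taken.add(best)
                rows.append((d.confidence, img, 1))
            else:
                rows.append((d.confidence, img, 0))
    if n_gt == 0:
        return None
    rows.sort(key=lambda r: (-r[0], r[1]))
    ap, prev_recall, best_prec = 0.0, 0.0, []
    tp = 0
    pr = []
    for i, (_, _, is_tp) in enumerate(rows, start=1):
        tp += is_tp
        pr.append((tp / n_gt, tp / i))
    # integrate max-precision-to-the-right over each recall increment
    ap = 0.0
    prev_r = 0.0
    for j, (r, _) in enumerate(pr):
        if r > prev_r:
            p_max = max(p for (r2, p) in pr[j:])
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap


# ---------------------------------------------------------------------------
# Cohen's kappa


class TestKappa:
    def test_identical_one(self):
        assert cohens_kappa([5, 4, 0, 3], [5, 4, 0, 3]) == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        # p_o = 0.5; marginals are uniform -> p_e = 0.5 -> kappa = 0
        assert cohens_kappa([5, 5, 0, 0], [5, 0, 5, 0]) == pytest.approx(0.0)

    def test_degenerate_constant_lists(self):
        # both raters constant and identical: p_o = p_e = 1 -> 0/0 -> 0
        with pytest.warns(UserWarning):
            assert cohens_kappa([3, 3, 3], [3, 3, 3]) == 0.0
        # constant but different: p_e = 0, so kappa is plain 0 (no warning)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert cohens_kappa([3, 3, 3], [5, 5, 5]) == 0.0

    def test_symmetric(self, rng):
        a = rng.integers(0, 6, size=50).tolist()
        b = rng.integers(0, 6, size=50).tolist()
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_against_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(10):
            a = rng.integers(0, 6, size=40)
            b = np.where(rng.random(40) < 0.7, a, rng.integers(0, 6, size=40))
            assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1])


# ---------------------------------------------------------------------------
# classification report


class TestClassificationReport:
    def test_perfectly_separated(self):
        probs = np.eye(3)[[0, 1, 2, 0, 1, 2]] * 0.94 + 0.02
        labels = [0, 1, 2, 0, 1, 2]
        rep = classification_report(probs, labels)
        assert rep["accuracy"] == 1.0
        assert all(v == 1.0 for v in rep["auc_per_class"].values())
        assert rep["macro_auc"] == 1.0

    def test_random_probs_auc_half(self):
        rng = np.random.default_rng(0)
        n = 3000
        probs = rng.dirichlet(np.ones(3), size=n)
        labels = rng.integers(0, 3, size=n)
        rep = classification_report(probs, labels)
        assert abs(rep["macro_auc"] - 0.5) < 0.03

    def test_confusion_matrix_row_sums(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(3), size=200)
        labels = rng.integers(0, 3, size=200)
        rep = classification_report(probs, labels)
        cm = rep["confusion_matrix"]
        for c in range(3):
            assert cm[c].sum() == int((labels == c).sum())

    def test_absent_class_excluded_with_warning(self):
        probs = np.array([[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.3, 0.6, 0.1]])
        labels = [0, 1, 1]  # class 2 absent
        with pytest.warns(UserWarning):
            rep = classification_report(probs, labels)
        assert 2 not in rep["auc_per_class"]

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            classification_report(np.array([[0.5, 0.2, 0.2]]), [0])
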