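import math

import numpy as np
import pytest

from echoqc.lvvc import (
    CardiacCycle,
    KeyframeLabel,
    Phase,
    PhaseCurve,
    ValidationError,
    extract_keyframes,
    find_complete_cycles,
    labels_from_json,
    labels_to_json,
    lvvc_ground_truth,
    select_qc_targets,
    validate_labels,
)

ED, ES = Phase.ED, Phase.ES


def kf(frame, phase):
    return KeyframeLabel(frame, phase)


def labels_eded():
    return [kf(0, ED), kf(10, ES), kf(20, ED)]


# ---------------------------------------------------------------------------
# ground-truth curve construction


class TestGroundTruthCurve:
    def test_endpoints_pinned(self):
        c = lvvc_ground_truth(labels_eded(), 21)
        assert c.values[0] == 1.0
        assert c.values[10] == -1.0
        assert c.values[20] == 1.0

    def test_midphase_zeros(self):
        c = lvvc_ground_truth(labels_eded(), 21)
        assert c.values[5] == pytest.approx(0.0, abs=1e-12)
        assert c.values[15] == pytest.approx(0.0, abs=1e-12)

    def test_quarter_phase_value(self):
        # x = 12.5 lies in the diastole segment ES@10 -> ED@20; independent
        # scalar evaluation of the segment sinusoid:
        expected = math.sin(1.5 * math.pi - math.pi * (10 - 12.5) / (20 - 10))
        assert expected == pytest.approx(-math.sqrt(2) / 2)
        c = lvvc_ground_truth(labels_eded(), 26)
        x = np.arange(26, dtype=float)
        fine = np.sin(1.5 * np.pi - np.pi * (10 - x) / 10.0)
        # frame 12 and 13 bracket the quarter-phase point
        assert c.values[12] == pytest.approx(fine[12])
        assert c.values[13] == pytest.approx(fine[13])

    def test_interior_continuity(self):
        # the left and right segment formulas agree at every interior keyframe
        from echoqc.lvvc import _segment_value

        labels = [kf(0, ES), kf(7, ED), kf(19, ES), kf(30, ED)]
        for f1, f2, f3 in zip(labels, labels[1:], labels[2:]):
            x = np.array([float(f2.frame_index)])
            left = _segment_value(x, f1, f2)[0]
            right = _segment_value(x, f2, f3)[0]
            assert abs(left - right) < 1e-9

    def test_bounded(self):
        labels = [kf(0, ES), kf(9, ED), kf(23, ES), kf(31, ED), kf(44, ES)]
        c = lvvc_ground_truth(labels, 45)
        assert c.values.min() >= -1.0 - 1e-12
        assert c.values.max() <= 1.0 + 1e-12

    def test_mask_outside_span(self):
        c = lvvc_ground_truth([kf(5, ED), kf(15, ES)], 30)
        assert not c.mask[:5].any()
        assert c.mask[5:16].all()
        assert not c.mask[16:].any()

    def test_extrapolation_is_masked_and_bounded(self):
        c = lvvc_ground_truth([kf(5, ED), kf(15, ES)], 30, extrapolate=True)
        assert not c.mask[:5].any() and not c.mask[16:].any()
        assert np.abs(c.values).max() <= 1.0 + 1e-12
        # extrapolated prefix continues the systole sinusoid
        assert c.values[4] == pytest.approx(np.sin(1.5 * np.pi + np.pi * (4 - 15) / 10))

    def test_errors(self):
        with pytest.raises(ValidationError):
            lvvc_ground_truth([kf(0, ED)], 10)
        with pytest.raises(ValidationError):
            lvvc_ground_truth([kf(0, ED), kf(0, ES)], 10)
        with pytest.raises(ValidationError):
            lvvc_ground_truth(labels_eded(), 20)  # n_frames too small

    def test_validate_rejects_non_alternating(self):
        with pytest.raises(ValidationError):
            validate_labels([kf(0, ED), kf(5, ED)])
        with pytest.raises(ValidationError):
            validate_labels([kf(5, ED), kf(3, ES)])


# ---------------------------------------------------------------------------
# keyframe extraction


class TestExtractKeyframes:
    def test_inverts_ground_truth(self):
        c = lvvc_ground_truth(labels_eded(), 21)
        assert extract_keyframes(c) == labels_eded()

    def test_analytic_sine(self):
        # sin(3pi/2 + 2pi t / 20) = -cos(2pi t / 20): ED (maxima) at
        # t = 10 + 20k, ES (minima) at t = 20k
        y = np.sin(1.5 * np.pi + 2 * np.pi * np.arange(60) / 20.0)
        got = extract_keyframes(y, smooth_window=1)
        assert [(k.frame_index, k.phase) for k in got] == [
            (0, ES), (10, ED), (20, ES), (30, ED), (40, ES), (50, ED),
        ]

    def test_min_separation_keeps_higher(self):
        y = np.zeros(30)
        y[10], y[12], y[20] = 1.0, 0.8, -1.0
        got = extract_keyframes(y, min_separation=5, smooth_window=1)
        eds = [k.frame_index for k in got if k.phase is ED]
        assert eds == [10]

    def test_constant_curve_empty(self):
        assert extract_keyframes(np.zeros(40), smooth_window=1) == []

    def test_alternation_enforced(self):
        got = extract_keyframes(
            np.sin(1.5 * np.pi + 2 * np.pi * np.arange(100) / 24.0), smooth_window=3
        )
        for a, b in zip(got, got[1:]):
            assert a.phase != b.phase
            assert a.frame_index < b.frame_index

    def test_errors(self):
        with pytest.raises(ValidationError):
            extract_keyframes(np.array([]))
        with pytest.raises(ValidationError):
            extract_keyframes(np.zeros(10), min_separation=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_random_labels(self, seed):
        rng = np.random.default_rng(seed)
        gaps = rng.integers(4, 18, size=rng.integers(2, 7))
        idx = np.concatenate([[0], np.cumsum(gaps)])
        first = ED if rng.random() < 0.5 else ES
        labels = [
            kf(int(f), first if i % 2 == 0 else first.opposite)
            for i, f in enumerate(idx)
        ]
        n = int(idx[-1]) + 1
        got = extract_keyframes(lvvc_ground_truth(labels, n), smooth_window=1)
        assert got == labels


# ---------------------------------------------------------------------------
# cycle finding and QC target selection


class TestCycles:
    def test_single_cycle(self):
        cycles = find_complete_cycles([kf(3, ED), kf(12, ES), kf(24, ED)])
        assert len(cycles) == 1
        assert cycles[0].pattern.value == "ED_ES_ED"

    def test_incomplete_pair(self):
        assert find_complete_cycles([kf(3, ED), kf(12, ES)]) == []

    def test_overlapping_cycles(self):
        cycles = find_complete_cycles([kf(2, ES), kf(10, ED), kf(20, ES), kf(30, ED)])
        assert len(cycles) == 2
        assert cycles[0].pattern.value == "ES_ED_ES"
        assert cycles[1].pattern.value == "ED_ES_ED"
        assert (cycles[0].start.frame_index, cycles[0].mid.frame_index,
                cycles[0].end.frame_index) == (2, 10, 20)

    def test_count_matches_length(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            m = int(rng.integers(0, 8))
            idx = np.cumsum(rng.integers(4, 12, size=m)) if m else []
            labels = [kf(int(f), ED if i % 2 == 0 else ES) for i, f in enumerate(idx)]
            assert len(find_complete_cycles(labels)) == max(0, len(labels) - 2)

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_brute_force(self, seed):
        """Sliding-window cycles match brute-force enumeration of all index
        triples forming an alternating consecutive pattern."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 9))
        idx = np.cumsum(rng.integers(4, 15, size=m))
        first = ED if rng.random() < 0.5 else ES
        labels = [kf(int(f), first if i % 2 == 0 else first.opposite)
                  for i, f in enumerate(idx)]

        got = {
            (c.start.frame_index, c.mid.frame_index, c.end.frame_index)
            for c in find_complete_cycles(labels)
        }
        # brute force: all i<j<k CONSECUTIVE triples with X-Y-X phases
        expected = set()
        for i in range(len(labels)):
            for j in range(len(labels)):
                for k in range(len(labels)):
                    if not (i < j < k) or (j - i, k - j) != (1, 1):
                        continue
                    a, b, c = labels[i], labels[j], labels[k]
                    if a.phase == c.phase != b.phase:
                        expected.add((a.frame_index, b.frame_index, c.frame_index))
        assert got == expected


class TestQCTargets:
    def test_ed_es_ed(self):
        cyc = find_complete_cycles([kf(3, ED), kf(12, ES), kf(24, ED)])[0]
        t = select_qc_targets(cyc)
        assert (t.ed_frame, t.es_frame) == (3, 12)

    def test_es_ed_es(self):
        cyc = find_complete_cycles([kf(2, ES), kf(10, ED), kf(20, ES)])[0]
        t = select_qc_targets(cyc)
        assert (t.ed_frame, t.es_frame) == (10, 2)

    def test_targets_subset_of_labels(self):
        labels = [kf(0, ED), kf(9, ES), kf(22, ED)]
        t = select_qc_targets(find_complete_cycles(labels)[0])
        frames = {k.frame_index for k in labels}
        assert {t.ed_frame, t.es_frame} <= frames


# ---------------------------------------------------------------------------
# JSON interchange


def test_labels_json_round_trip():
    labels = [kf(0, ES), kf(11, ED), kf(25, ES)]
    text = labels_to_json("vid7", 30, labels)
    vid, n, got = labels_from_json(text)
    assert (vid, n) == ("vid7", 30)
    assert got == labels


def test_phase_curve_csv_round_trip(tmp_path):
    c = lvvc_ground_truth([kf(2, ED), kf(9, ES)], 15)
    p = tmp_path / "curve.csv"
    c.to_csv(p)
    back = PhaseCurve.from_csv(p)
    np.testing.assert_allclose(back.values, c.values)
    np.testing.assert_array_equal(back.mask, c.mask)


def test_curve_out_of_range_rejected():
    with pytest.raises(ValidationError):
        PhaseCurve(values=np.array([0.0, 1.5]))


def test_cycle_invariants():
    with pytest.raises(ValidationError):
        CardiacCycle(start=kf(0, ED), mid=kf(5, ED), end=kf(9, ED))
    with pytest.raises(ValidationError):
        CardiacCycle(start=kf(9, ED), mid=kf(5, ES), end=kf(0, ED))
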