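"""The sliding-window I-DT classifier against its brute-force oracle."""

import numpy as np
import pytest

from vrfix import GazeRecording, IDTParams, classified_point_mask, detect_fixations

from conftest import random_stream
from reference import ref_detect


PARAMS = IDTParams(dispersion_th=1.0, time_window=0.25, freq_floor=30.0)


def make_recording(t, gaze, head=None):
    t = np.asarray(t, float)
    gaze = np.asarray(gaze, float)
    head = np.zeros((len(t), 3)) if head is None else np.asarray(head, float)
    return GazeRecording(
        subject_id="s",
        t=t,
        gaze=gaze,
        head=head,
        left_blink=np.zeros(len(t)),
        right_blink=np.zeros(len(t)),
    )


def constant_gaze(duration, rate, start=0.0, direction=(0.0, 0.0, 1.0), dist=2.0):
    n = int(round(duration * rate))
    t = start + np.arange(n) / rate
    gaze = np.tile(np.asarray(direction, float) * dist, (n, 1))
    return t, gaze


class TestDetectFixations:
    def test_constant_gaze_single_fixation(self):
        t, gaze = constant_gaze(1.0, 90.0)
        rec = make_recording(t, gaze)
        fx = detect_fixations(rec, PARAMS)
        assert len(fx) == 1
        f = fx[0]
        assert (f.start, f.stop) == (0, len(rec))
        assert f.dispersion == 0.0
        assert f.duration >= PARAMS.time_window

    def test_two_separated_clusters(self):
        t1, g1 = constant_gaze(0.5, 60.0)
        # 40 degrees away, 3 in-flight samples between the clusters
        d2 = np.array([np.sin(np.radians(40.0)), 0.0, np.cos(np.radians(40.0))])
        t_sacc = t1[-1] + np.array([1, 2, 3]) / 60.0
        fr = np.array([0.25, 0.5, 0.75])[:, None]
        g_sacc = (1 - fr) * g1[-1] + fr * (2.0 * d2)
        t2, g2 = constant_gaze(0.5, 60.0, start=t_sacc[-1] + 1 / 60.0, direction=d2)
        rec = make_recording(
            np.concatenate([t1, t_sacc, t2]), np.concatenate([g1, g_sacc, g2])
        )
        fx = detect_fixations(rec, PARAMS)
        assert len(fx) == 2
        sacc_idx = set(range(len(t1), len(t1) + 3))
        members = set()
        for f in fx:
            members.update(f.sample_indices)
        assert members.isdisjoint(sacc_idx)

    def test_frequency_gap_splits_run(self):
        # constant gaze with one 0.05 s gap (> 1/30 s) in the middle
        t = np.concatenate([np.arange(13) / 45.0, 0.05 + 12 / 45.0 + np.arange(13) / 45.0])
        gaze = np.tile([0.0, 0.0, 2.0], (26, 1))
        rec = make_recording(t, gaze)
        fx = detect_fixations(rec, PARAMS)
        assert len(fx) == 2  # each sub-run spans >= 0.25 s on its own
        for f in fx:
            gaps = np.diff(rec.t[f.start : f.stop])
            assert gaps.max() <= PARAMS.max_gap
        # shorten the second sub-run below the window: only one fixation left
        rec2 = make_recording(t[:16], gaze[:16])
        fx2 = detect_fixations(rec2, PARAMS)
        assert len(fx2) == 1
        assert fx2[0].stop <= 13

    def test_shorter_than_window_yields_empty(self):
        t, gaze = constant_gaze(0.2, 45.0)
        assert detect_fixations(make_recording(t, gaze), PARAMS) == []

    def test_wide_threshold_single_fixation(self):
        rec = random_stream(3, n=300, gap_prob=0.0)
        fx = detect_fixations(rec, IDTParams(180.0, 0.25, 30.0))
        assert len(fx) == 1
        assert (fx[0].start, fx[0].stop) == (0, len(rec))

    def test_deterministic(self):
        rec = random_stream(9, n=400)
        a = detect_fixations(rec, PARAMS)
        b = detect_fixations(rec, PARAMS)
        assert [(f.start, f.stop) for f in a] == [(f.start, f.stop) for f in b]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_reference(self, seed):
        rec = random_stream(seed, n=500)
        got = [(f.start, f.stop) for f in detect_fixations(rec, PARAMS)]
        expected = ref_detect(
            rec.t.tolist(),
            rec.gaze.tolist(),
            rec.head.tolist(),
            PARAMS.dispersion_th,
            PARAMS.time_window,
            PARAMS.freq_floor,
        )
        assert got == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_emitted_fixations_satisfy_invariants(self, seed):
        from vrfix import angular_dispersion

        rec = random_stream(100 + seed, n=600, step_deg=0.6)
        fx = detect_fixations(rec, PARAMS)
        prev_stop = 0
        for f in fx:
            assert f.start >= prev_stop  # disjoint and ordered
            prev_stop = f.stop
            assert f.duration >= PARAMS.time_window
            assert np.diff(rec.t[f.start : f.stop]).max() <= PARAMS.max_gap
            # re-check dispersion post-hoc with the emitted head mean
            d = angular_dispersion(rec.gaze[f.start : f.stop], f.head_mean)
            assert d <= PARAMS.dispersion_th + 1e-9
            assert d == pytest.approx(f.dispersion, abs=1e-12)
            np.testing.assert_allclose(
                f.centroid, rec.gaze[f.start : f.stop].mean(axis=0)
            )


class TestClassifiedPointMask:
    def test_no_fixations_all_false(self):
        rec = random_stream(2, n=50)
        assert not classified_point_mask(rec, []).any()

    def test_full_cover_all_true(self):
        t, gaze = constant_gaze(1.0, 45.0)
        rec = make_recording(t, gaze)
        fx = detect_fixations(rec, PARAMS)
        assert classified_point_mask(rec, fx).all()

    def test_count_conservation(self):
        rec = random_stream(4, n=500)
        fx = detect_fixations(rec, PARAMS)
        mask = classified_point_mask(rec, fx)
        assert mask.sum() == sum(f.n_samples for f in fx)
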