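"""The guided two-panel protocol generator and its ground truth."""

import numpy as np
import pytest

from vrfix import (
    IDTParams,
    LIT_SEQUENCE,
    SimParams,
    default_protocol,
    detect_fixations,
    pct_in_aoi,
    remove_blinks,
    simulate_cohort,
    simulate_session,
    trim_to_protocol,
)


def azimuth_deg(point, viewer):
    d = np.asarray(point) - viewer
    return np.degrees(np.arctan2(d[0], d[2]))


class TestDefaultProtocol:
    def test_sequence_and_timing(self):
        prot = default_protocol()
        assert len(prot.sequence) == 15
        assert prot.sequence == LIT_SEQUENCE
        assert prot.guided_duration == pytest.approx(45.0)
        events = prot.events()
        assert len(events) == 15
        total = sum(e.t_off - e.t_on for e in events)
        assert total == pytest.approx(45.0)
        assert events[0].t_on == pytest.approx(prot.lead_in)

    def test_panel_angular_extents(self):
        prot = default_protocol()
        front = [r for r in prot.regions if r.aoi_id <= 16]
        side = [r for r in prot.regions if r.aoi_id >= 17]
        fa = [
            azimuth_deg(r.center + s * r.edge_u, prot.viewer)
            for r in front
            for s in (-1.0, 1.0)
        ]
        assert min(fa) == pytest.approx(-14.93, abs=0.5)
        assert max(fa) == pytest.approx(14.93, abs=0.5)
        sa = [
            azimuth_deg(r.center + s * r.edge_u, prot.viewer)
            for r in side
            for s in (-1.0, 1.0)
        ]
        assert min(sa) == pytest.approx(25.02, abs=0.5)
        assert max(sa) == pytest.approx(45.00, abs=0.5)

    def test_region_grid_structure(self):
        prot = default_protocol()
        assert len(prot.regions) == 32
        assert sorted(r.aoi_id for r in prot.regions) == list(range(1, 33))
        # squares are equal-size and orthogonal by construction
        for r in prot.regions:
            assert abs(r.edge_u @ r.edge_v) < 1e-12


class TestSimulateSession:
    def test_same_seed_bit_identical(self):
        a = simulate_session(seed=5)
        b = simulate_session(seed=5)
        np.testing.assert_array_equal(a.recording.t, b.recording.t)
        np.testing.assert_array_equal(a.recording.gaze, b.recording.gaze)
        np.testing.assert_array_equal(a.recording.head, b.recording.head)
        assert a.labels.equals(b.labels)

    def test_noiseless_recovery(self):
        params = SimParams(
            noise_sd_deg=0.0,
            blink_rate_per_min=0.0,
            dropout_rate_per_min=0.0,
            adherence=1.0,
        )
        sess = simulate_session(params=params, seed=2)
        rec, frac = remove_blinks(sess.recording)
        assert frac == 0.0
        rec = trim_to_protocol(rec, sess.events)
        fx = detect_fixations(rec, IDTParams(1.0, 0.25, 30.0))
        assert len(fx) == len(sess.protocol.sequence)
        assert pct_in_aoi([fx], sess.events, sess.protocol.regions) == 100.0

    def test_effective_rate_near_nominal(self):
        from vrfix import frequency_profile

        sess = simulate_session(seed=8)
        series = frequency_profile([sess.recording])
        assert abs(series.mean_hz.mean() - 45.0) < 2.0

    def test_blink_bookkeeping(self):
        sess = simulate_session(seed=12)
        _, frac = remove_blinks(sess.recording)
        labeled = float((sess.labels.cls == "blink").mean())
        assert frac > 0.0
        assert frac == pytest.approx(labeled)

    def test_labels_consistent_with_events(self):
        sess = simulate_session(seed=4)
        lab = sess.labels
        t = sess.recording.t
        fixation = lab.cls == "fixation"
        for idx in np.nonzero(fixation.to_numpy())[0]:
            lit = int(lab.lit_aoi.iloc[idx])
            # square 10 is lit twice, so match against every event of that id
            assert any(
                e.aoi_id == lit and e.t_on <= t[idx] <= e.t_off for e in sess.events
            )

    def test_ground_truth_segments_fit_noise_cone(self):
        from vrfix import angular_dispersion

        sess = simulate_session(seed=21)
        rec, lab = sess.recording, sess.labels
        cone = 3.0 * 0.3  # dispersion budget for the default noise scale
        for event in sess.events:
            m = (
                (lab.cls == "fixation").to_numpy()
                & (rec.t >= event.t_on)
                & (rec.t <= event.t_off)
            )
            if m.sum() < 2:
                continue
            disp = angular_dispersion(rec.gaze[m], rec.head[m].mean(axis=0))
            assert disp <= cone

    def test_lead_in_outside_event_log(self):
        sess = simulate_session(seed=6)
        assert sess.events[0].t_on == pytest.approx(60.0)
        before = sess.recording.t < 60.0
        assert before.sum() > 0
        assert (sess.labels.cls[before].isin(["free", "blink"])).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(adherence=1.5)
        with pytest.raises(ValueError):
            SimParams(rate_hz=0.0)


class TestSimulateCohort:
    def test_distinct_subjects(self):
        sessions = simulate_cohort(3, seed=0)
        ids = [s.recording.subject_id for s in sessions]
        assert len(set(ids)) == 3
        assert not np.array_equal(
            sessions[0].recording.gaze[:50], sessions[1].recording.gaze[:50]
        )

    def test_shared_event_log(self):
        sessions = simulate_cohort(2, seed=0)
        assert sessions[0].events == sessions[1].events
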