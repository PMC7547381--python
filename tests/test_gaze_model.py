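"""Angular-dispersion geometry and container invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrfix import (
    DegenerateGeometryError,
    GazeRecording,
    GazeSample,
    IDTParams,
    angular_dispersion,
    direction_vectors,
)

from reference import ref_dispersion_deg


ORIGIN = np.zeros(3)


class TestDirectionVectors:
    def test_identity_case(self):
        out = direction_vectors(np.array([[1.0, 0.0, 0.0]]), ORIGIN)
        np.testing.assert_allclose(out, [[1.0, 0.0, 0.0]])

    def test_normalization(self):
        out = direction_vectors(np.array([[0.0, 2.0, 0.0]]), ORIGIN)
        np.testing.assert_allclose(out, [[0.0, 1.0, 0.0]])

    def test_degenerate_names_sample(self):
        pts = np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
        with pytest.raises(DegenerateGeometryError, match="sample 1"):
            direction_vectors(pts, np.array([0.5, 0.5, 0.5]))

    def test_accepts_gaze_samples(self):
        samples = [GazeSample(t=0.0, gaze=[0.0, 0.0, 3.0], head=[0.0, 0.0, 0.0])]
        np.testing.assert_allclose(
            direction_vectors(samples, ORIGIN), [[0.0, 0.0, 1.0]]
        )


class TestAngularDispersion:
    def test_single_point_is_zero(self):
        assert angular_dispersion(np.array([[0.0, 0.0, 1.0]]), ORIGIN) == 0.0

    def test_orthogonal_pair_is_90(self):
        pts = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        assert angular_dispersion(pts, ORIGIN) == pytest.approx(90.0)

    def test_matches_bruteforce_on_random_directions(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        expected = ref_dispersion_deg(pts.tolist(), [0.0, 0.0, 0.0])
        assert angular_dispersion(pts, ORIGIN) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(5, 3)) + np.array([0.0, 0.0, 5.0])
        perm = rng.permutation(5)
        assert angular_dispersion(pts, ORIGIN) == pytest.approx(
            angular_dispersion(pts[perm], ORIGIN), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_rigid_rotation_invariant(self, seed):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(5, 3)) + np.array([0.0, 0.0, 5.0])
        origin = rng.normal(size=3) * 0.1
        rot = Rotation.random(rng=rng).as_matrix()
        assert angular_dispersion(pts @ rot.T, rot @ origin) == pytest.approx(
            angular_dispersion(pts, origin), abs=1e-7
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_monotone_under_superset(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3)) + np.array([0.0, 0.0, 5.0])
        assert angular_dispersion(pts[:-1], ORIGIN) <= angular_dispersion(
            pts, ORIGIN
        ) + 1e-12

    def test_antipodal_pair_clamped(self):
        # cos can overshoot +/-1 in float; arccos must not produce NaN
        pts = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        assert angular_dispersion(pts, ORIGIN) == pytest.approx(180.0)


class TestContainers:
    def test_sample_validates_blink_range(self):
        with pytest.raises(ValueError, match="left_blink"):
            GazeSample(t=0.0, gaze=[0, 0, 1], head=[0, 0, 0], left_blink=1.2)

    def test_sample_rejects_zero_ray(self):
        with pytest.raises(DegenerateGeometryError):
            GazeSample(t=0.0, gaze=[1.0, 2.0, 3.0], head=[1.0, 2.0, 3.0])

    def test_recording_requires_increasing_time(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GazeRecording(
                subject_id="x",
                t=[0.0, 0.1, 0.1],
                gaze=np.tile([0.0, 0.0, 1.0], (3, 1)),
                head=np.zeros((3, 3)),
                left_blink=np.zeros(3),
                right_blink=np.zeros(3),
            )

    def test_recording_roundtrips_samples(self):
        samples = [
            GazeSample(t=0.0, gaze=[0, 0, 2], head=[0, 0, 0], left_blink=0.1),
            GazeSample(t=0.5, gaze=[1, 0, 2], head=[0, 0.1, 0], right_blink=0.2),
        ]
        rec = GazeRecording.from_samples("s", samples)
        assert len(rec) == 2
        back = rec.sample(1)
        assert back.t == 0.5
        np.testing.assert_allclose(back.gaze, [1, 0, 2])
        assert back.right_blink == 0.2

    def test_params_validation(self):
        with pytest.raises(ValueError):
            IDTParams(dispersion_th=0.0, time_window=0.25)
        with pytest.raises(ValueError):
            IDTParams(dispersion_th=200.0, time_window=0.25)
        assert IDTParams(1.0, 0.25).max_gap == pytest.approx(1.0 / 30.0)
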