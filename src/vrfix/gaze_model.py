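"""Core data types and 3-D angular geometry for VR-centered gaze analysis.

In head-mounted-display eye tracking the device reports, per sample, the 3-D
point where the gaze ray strikes the virtual scene together with the 3-D head
position, both in world coordinates.  A fixation is a run of consecutive
samples whose gaze directions -- measured from a common, *averaged* head
origin -- stay inside a small angular cone for a minimum amount of time.
This module holds the sample/recording/fixation containers and the angular
dispersion measure those definitions rest on.

The dispersion of a set of samples with respect to a head origin ``h_bar`` is
the largest pairwise angle between the direction vectors ``d_n = g_n - h_bar``
(``g_n`` the gaze impact points), i.e. ``max_{i,j} arccos(d_i . d_j /
|d_i||d_j|)``, reported in degrees.

Coordinates are treated as an abstract right-handed Cartesian frame in
meters.  Handedness of the source engine does not affect angles, so no
conversion is attempted.  Angles are degrees at every public boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence, Union

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "GazeSample",
    "GazeRecording",
    "Fixation",
    "IDTParams",
    "direction_vectors",
    "angular_dispersion",
]


class DegenerateGeometryError(ValueError):
    """A gaze point coincides with the head origin (zero-length ray)."""


def _as_point(value, name: str) -> np.ndarray:
    p = np.asarray(value, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} must be finite, got {p}")
    return p


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze/head/eyelid record.

    Parameters
    ----------
    t : float
        Seconds from session start (finite, non-negative).
    gaze : array-like, shape (3,)
        World-frame impact point of the gaze ray, meters.
    head : array-like, shape (3,)
        World-frame head position, meters.  Must differ from ``gaze``.
    left_blink, right_blink : float
        Eyelid-closure coefficients in [0, 1]; 1 means fully closed.
    """

    t: float
    gaze: np.ndarray
    head: np.ndarray
    left_blink: float = 0.0
    right_blink: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gaze", _as_point(self.gaze, "gaze"))
        object.__setattr__(self, "head", _as_point(self.head, "head"))
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"t must be finite and >= 0, got {self.t}")
        for name in ("left_blink", "right_blink"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if np.array_equal(self.gaze, self.head):
            raise DegenerateGeometryError("gaze point equals head position")


@dataclass
class GazeRecording:
    """An ordered per-subject gaze stream backed by numpy arrays.

    Timestamps must be strictly increasing.  ``gaze`` and ``head`` are
    ``(n, 3)`` arrays; blink coefficients are ``(n,)`` arrays in [0, 1].
    """

    subject_id: str
    t: np.ndarray
    gaze: np.ndarray
    head: np.ndarray
    left_blink: np.ndarray
    right_blink: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        self.left_blink = np.asarray(self.left_blink, dtype=float)
        self.right_blink = np.asarray(self.right_blink, dtype=float)
        n = self.t.size
        if self.t.shape != (n,):
            raise ValueError("t must be a 1-D array")
        for name in ("gaze", "head"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        for name in ("left_blink", "right_blink"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            if n and (np.min(arr) < 0.0 or np.max(arr) > 1.0):
                bad = int(np.argmax((arr < 0) | (arr > 1)))
                raise ValueError(
                    f"{name} out of [0, 1] at sample {bad}: {arr[bad]}"
                )
        if n:
            if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
                raise ValueError("timestamps must be finite and >= 0")
            gaps = np.diff(self.t)
            if np.any(gaps <= 0):
                bad = int(np.argmax(gaps <= 0))
                raise ValueError(
                    f"timestamps must be strictly increasing (violated at sample {bad + 1})"
                )
            same = np.all(self.gaze == self.head, axis=1)
            if np.any(same):
                bad = int(np.argmax(same))
                raise DegenerateGeometryError(
                    f"gaze point equals head position at sample {bad}"
                )

    # -- container protocol ------------------------------------------------

    def __len__(self) -> int:
        return self.t.size

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def sample(self, i: int) -> GazeSample:
        return GazeSample(
            t=float(self.t[i]),
            gaze=self.gaze[i],
            head=self.head[i],
            left_blink=float(self.left_blink[i]),
            right_blink=float(self.right_blink[i]),
        )

    def __iter__(self) -> Iterator[GazeSample]:
        for i in range(len(self)):
            yield self.sample(i)

    def select(self, index) -> "GazeRecording":
        """Return a new recording with the samples selected by a boolean
        mask or integer index array (order preserved)."""
        return GazeRecording(
            subject_id=self.subject_id,
            t=self.t[index],
            gaze=self.gaze[index],
            head=self.head[index],
            left_blink=self.left_blink[index],
            right_blink=self.right_blink[index],
        )

    @classmethod
    def from_samples(cls, subject_id: str, samples: Sequence[GazeSample]) -> "GazeRecording":
        if len(samples) == 0:
            z = np.zeros((0, 3))
            return cls(subject_id, np.zeros(0), z, z, np.zeros(0), np.zeros(0))
        return cls(
            subject_id=subject_id,
            t=np.array([s.t for s in samples], dtype=float),
            gaze=np.stack([s.gaze for s in samples]),
            head=np.stack([s.head for s in samples]),
            left_blink=np.array([s.left_blink for s in samples], dtype=float),
            right_blink=np.array([s.right_blink for s in samples], dtype=float),
        )


@dataclass(frozen=True)
class IDTParams:
    """Thresholds of the dispersion-based (I-DT) fixation classifier.

    Attributes
    ----------
    dispersion_th : float
        Maximum angular dispersion of a fixation, degrees (0, 180].
    time_window : float
        Minimum fixation duration, seconds.
    freq_floor : float
        Minimum effective acquisition rate, Hz.  Runs containing an
        inter-sample gap longer than ``1 / freq_floor`` seconds cannot
        support a fixation.  Default 30 Hz.
    blink_cutoff : float
        Eyelid coefficient above which (in either eye) a sample counts as a
        blink.  Default 0.75.
    """

    dispersion_th: float
    time_window: float
    freq_floor: float = 30.0
    blink_cutoff: float = 0.75

    def __post_init__(self) -> None:
        for name in ("dispersion_th", "time_window", "freq_floor", "blink_cutoff"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.dispersion_th > 180.0:
            raise ValueError("dispersion_th cannot exceed 180 degrees")

    @property
    def max_gap(self) -> float:
        """Longest admissible inter-sample interval, seconds."""
        return 1.0 / self.freq_floor


@dataclass(frozen=True)
class Fixation:
    """A classified fixation: a contiguous sample range of one recording.

    ``start``/``stop`` delimit the half-open member index range
    ``[start, stop)``.  ``centroid`` is the mean gaze impact point of the
    members, ``head_mean`` the averaged head position used as the ray origin
    at emission time, and ``dispersion`` the members' maximum pairwise angle
    (degrees) measured from ``head_mean``.
    """

    t_start: float
    t_end: float
    start: int
    stop: int
    centroid: np.ndarray
    head_mean: np.ndarray
    dispersion: float

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("fixation must contain at least one sample")
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")
        object.__setattr__(self, "centroid", _as_point(self.centroid, "centroid"))
        object.__setattr__(self, "head_mean", _as_point(self.head_mean, "head_mean"))

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    @property
    def sample_indices(self) -> range:
        return range(self.start, self.stop)


SampleSet = Union[GazeRecording, Sequence[GazeSample], np.ndarray]


def _gaze_array(samples: SampleSet) -> np.ndarray:
    if isinstance(samples, GazeRecording):
        return samples.gaze
    if isinstance(samples, np.ndarray):
        arr = np.asarray(samples, dtype=float)
    elif len(samples) and isinstance(samples[0], GazeSample):
        arr = np.stack([s.gaze for s in samples])
    else:
        arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1 and arr.size == 3:
        arr = arr.reshape(1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3) gaze points, got shape {arr.shape}")
    return arr


def direction_vectors(samples: SampleSet, head_mean) -> np.ndarray:
    """Unit gaze-direction vectors from an averaged head origin.

    Each row is ``(gaze_n - head_mean)`` normalized to unit length.  Raises
    :class:`DegenerateGeometryError` (naming the offending sample index) if
    any gaze point coincides with ``head_mean``.
    """
    gaze = _gaze_array(samples)
    origin = _as_point(head_mean, "head_mean")
    d = gaze - origin
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0.0):
        bad = int(np.argmax(norms == 0.0))
        raise DegenerateGeometryError(
            f"gaze point equals head_mean at sample {bad}: zero-length direction"
        )
    return d / norms[:, None]


def angular_dispersion(samples: SampleSet, head_mean) -> float:
    """Maximum pairwise angle (degrees) among gaze directions.

    Directions are taken from ``head_mean``; the angle between two
    directions is ``arccos`` of their dot product, clamped to [-1, 1] to
    guard against floating-point overshoot.  A single sample has dispersion
    0.  Exact O(n^2) evaluation, no bounding-cone shortcut.
    """
    u = direction_vectors(samples, head_mean)
    if u.shape[0] < 2:
        return 0.0
    cos = u @ u.T
    return float(np.degrees(np.arccos(np.clip(cos.min(), -1.0, 1.0))))
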