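"""Cohort-level calibration features and area-of-interest scoring.

Four features summarise how a given (dispersion threshold, time window)
pair behaves on a cohort: the mean number of fixations per subject, the
percentage of samples classified into fixations, the mean fixation
duration, and -- for guided protocols with lit areas of interest -- the
percentage of fixations whose centers land inside the concurrently lit
AoI.  All four are averaged across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gaze_model import Fixation, GazeRecording
from .idt import classified_point_mask

__all__ = [
    "AoIEvent",
    "AoIRegion",
    "FeatureVector",
    "n_fixations",
    "pct_points",
    "mean_fix_time",
    "pct_in_aoi",
    "compute_features",
]


@dataclass(frozen=True)
class AoIEvent:
    """A lit interval of one area of interest: [t_on, t_off] seconds."""

    aoi_id: int
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if not (self.t_on < self.t_off):
            raise ValueError(f"t_on must precede t_off, got [{self.t_on}, {self.t_off}]")

    def contains_time(self, t: float) -> bool:
        return self.t_on <= t <= self.t_off


@dataclass(frozen=True)
class AoIRegion:
    """A 3-D rectangle: center plus two orthogonal half-extent edge vectors.

    ``edge_u`` and ``edge_v`` span the rectangle's plane; their magnitudes
    are the half-widths along each axis.
    """

    aoi_id: int
    center: np.ndarray
    edge_u: np.ndarray
    edge_v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("center", "edge_u", "edge_v"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        lu = np.linalg.norm(self.edge_u)
        lv = np.linalg.norm(self.edge_v)
        if lu == 0 or lv == 0:
            raise ValueError("edge vectors must be nonzero")
        if abs(float(self.edge_u @ self.edge_v)) > 1e-9 * lu * lv:
            raise ValueError("edge_u and edge_v must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        nrm = np.cross(self.edge_u, self.edge_v)
        return nrm / np.linalg.norm(nrm)

    def contains(self, point, plane_tol: float = 0.05) -> bool:
        """True if ``point`` projects inside the rectangle and lies within
        ``plane_tol`` meters of its plane."""
        d = np.asarray(point, dtype=float) - self.center
        lu = np.linalg.norm(self.edge_u)
        lv = np.linalg.norm(self.edge_v)
        u = float(d @ self.edge_u) / lu
        v = float(d @ self.edge_v) / lv
        w = float(d @ self.normal)
        return abs(u) <= lu and abs(v) <= lv and abs(w) <= plane_tol


@dataclass(frozen=True)
class FeatureVector:
    """The four calibration features for one parameter pair."""

    n_fixations: float
    pct_points: float
    mean_fix_time: float
    pct_in_aoi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_fixations < 0:
            raise ValueError("n_fixations must be >= 0")
        for name in ("pct_points", "pct_in_aoi"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


FixationsBySubject = Sequence[Sequence[Fixation]]


def _check_cohort(fixations_by_subject: FixationsBySubject) -> None:
    if len(fixations_by_subject) == 0:
        raise ValueError("cohort features require at least one subject")


def n_fixations(fixations_by_subject: FixationsBySubject) -> float:
    """Mean number of fixations per subject."""
    _check_cohort(fixations_by_subject)
    return float(np.mean([len(fx) for fx in fixations_by_subject]))


def pct_points(
    recordings: Sequence[GazeRecording], fixations_by_subject: FixationsBySubject
) -> float:
    """Mean across subjects of the percentage of samples inside fixations."""
    _check_cohort(fixations_by_subject)
    if len(recordings) != len(fixations_by_subject):
        raise ValueError("recordings and fixation lists must align by subject")
    pcts = []
    for rec, fx in zip(recordings, fixations_by_subject):
        if len(rec) == 0:
            pcts.append(0.0)
            continue
        pcts.append(100.0 * float(classified_point_mask(rec, fx).mean()))
    return float(np.mean(pcts))


def mean_fix_time(fixations_by_subject: FixationsBySubject) -> float:
    """Mean across subjects of the per-subject mean fixation duration.

    Subjects with no fixations carry no defined mean duration and are
    excluded from the across-subject average; if no subject has any
    fixation the feature is 0.
    """
    _check_cohort(fixations_by_subject)
    per_subject = [
        float(np.mean([f.duration for f in fx]))
        for fx in fixations_by_subject
        if len(fx) > 0
    ]
    if not per_subject:
        return 0.0
    return float(np.mean(per_subject))


def _assigned_event(events: Sequence[AoIEvent], t_mid: float) -> Optional[AoIEvent]:
    for e in events:
        if e.contains_time(t_mid):
            return e
    return None


def pct_in_aoi(
    fixations_by_subject: FixationsBySubject,
    events: Sequence[AoIEvent],
    regions: Sequence[AoIRegion],
    plane_tol: float = 0.05,
) -> float:
    """Percentage of fixations whose centers lie inside the lit AoI.

    Each fixation is assigned to the event containing its temporal midpoint
    (fixations whose midpoint falls in no lit interval are excluded from
    the denominator).  An assigned fixation counts as *inside* when its
    centroid projects within the event's rectangle and sits within
    ``plane_tol`` meters of the rectangle's plane.  The per-subject
    percentages (inside / assigned) are then averaged across subjects;
    subjects with no assigned fixation are excluded, and the feature is 0
    when no subject has one.
    """
    _check_cohort(fixations_by_subject)
    events = list(events)
    by_id = {r.aoi_id: r for r in regions}
    missing = {e.aoi_id for e in events} - set(by_id)
    if missing:
        raise ValueError(f"regions missing for AoI ids {sorted(missing)}")
    pcts = []
    for fx in fixations_by_subject:
        assigned = 0
        inside = 0
        for f in fx:
            event = _assigned_event(events, 0.5 * (f.t_start + f.t_end))
            if event is None:
                continue
            assigned += 1
            if by_id[event.aoi_id].contains(f.centroid, plane_tol):
                inside += 1
        if assigned:
            pcts.append(100.0 * inside / assigned)
    if not pcts:
        return 0.0
    return float(np.mean(pcts))


def compute_features(
    recordings: Sequence[GazeRecording],
    fixations_by_subject: FixationsBySubject,
    events: Optional[Sequence[AoIEvent]] = None,
    regions: Optional[Sequence[AoIRegion]] = None,
    plane_tol: float = 0.05,
) -> FeatureVector:
    """Evaluate all features for one cohort; AoI feature only when events
    and regions are supplied."""
    aoi = None
    if events is not None and regions is not None:
        aoi = pct_in_aoi(fixations_by_subject, events, regions, plane_tol)
    return FeatureVector(
        n_fixations=n_fixations(fixations_by_subject),
        pct_points=pct_points(recordings, fixations_by_subject),
        mean_fix_time=mean_fix_time(fixations_by_subject),
        pct_in_aoi=aoi,
    )
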