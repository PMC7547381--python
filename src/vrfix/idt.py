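"""Dispersion-threshold (I-DT) fixation identification for VR-centered gaze.

The classifier slides a window over the sample stream:

1. A window is *seeded* with the shortest run of consecutive samples
   spanning at least ``time_window`` seconds.
2. The seed is rejected -- and the start advances by one sample -- if the
   run contains an inter-sample gap longer than ``1 / freq_floor`` seconds
   (the acquisition-frequency guard) or if its angular dispersion exceeds
   ``dispersion_th``.
3. An accepted window *grows* one sample at a time; every growth step
   re-averages the head origin over the enlarged member set and re-checks
   both the gap rule and the dispersion rule against that updated origin.
4. When no further sample can join, the window is emitted as a
   :class:`~vrfix.gaze_model.Fixation` and seeding restarts after its last
   sample.

The head origin is always the mean head position of the *current* window
members, re-averaged every time a candidate point is added, which
compensates for free head movement inside the virtual environment.  The
dispersion comparison is inclusive (a window exactly at the threshold
passes); the frequency guard is a strict per-gap rule, so a window can
never straddle a low-frequency dropout.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .gaze_model import Fixation, GazeRecording, IDTParams, angular_dispersion

__all__ = ["detect_fixations", "classified_point_mask"]


def _window_dispersion(gaze: np.ndarray, head: np.ndarray, a: int, b: int) -> float:
    """Dispersion of samples [a, b) about the mean head position of [a, b)."""
    head_mean = head[a:b].mean(axis=0)
    return angular_dispersion(gaze[a:b], head_mean)


def detect_fixations(recording: GazeRecording, params: IDTParams) -> List[Fixation]:
    """Classify fixations in a blink-filtered, trimmed recording.

    Returns temporally disjoint fixations in order.  Every emitted fixation
    spans at least ``params.time_window`` seconds, has dispersion at most
    ``params.dispersion_th`` degrees about its own averaged head position,
    and contains no internal gap longer than ``params.max_gap`` seconds.  A
    recording shorter than the time window yields an empty list.
    """
    t = recording.t
    gaze = recording.gaze
    head = recording.head
    n = t.size
    if n == 0:
        return []
    max_gap = params.max_gap
    th = params.dispersion_th
    w = params.time_window
    dt = np.diff(t)
    fixations: List[Fixation] = []

    i = 0
    while i < n:
        if t[i] + w > t[n - 1]:
            break  # no run starting here can span the time window
        # smallest j with t[j] - t[i] >= w
        j = int(np.searchsorted(t, t[i] + w, side="left"))
        if j >= n:
            break
        if np.any(dt[i:j] > max_gap) or _window_dispersion(gaze, head, i, j + 1) > th:
            i += 1  # classic I-DT: drop only the first sample
            continue
        k = j
        while k + 1 < n:
            if dt[k] > max_gap:
                break
            if _window_dispersion(gaze, head, i, k + 2) > th:
                break
            k += 1
        stop = k + 1
        head_mean = head[i:stop].mean(axis=0)
        fixations.append(
            Fixation(
                t_start=float(t[i]),
                t_end=float(t[k]),
                start=i,
                stop=stop,
                centroid=gaze[i:stop].mean(axis=0),
                head_mean=head_mean,
                dispersion=angular_dispersion(gaze[i:stop], head_mean),
            )
        )
        i = stop
    return fixations


def classified_point_mask(
    recording: GazeRecording, fixations: Sequence[Fixation]
) -> np.ndarray:
    """Boolean array: True exactly for samples belonging to some fixation."""
    mask = np.zeros(len(recording), dtype=bool)
    for f in fixations:
        mask[f.start : f.stop] = True
    return mask
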