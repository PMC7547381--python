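"""Blink removal, protocol trimming and acquisition-frequency analysis.

HMD-integrated eye trackers deliver gaze samples through the rendering loop,
so the effective rate fluctuates with scene complexity, and eyelid closures
corrupt the gaze ray.  Preprocessing therefore (1) drops samples whose
eyelid coefficient exceeds a blink cutoff in either eye, (2) restricts the
stream to the guided-task span (first lit square to last lit square), and
(3) summarises the per-second acquisition rate across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .gaze_model import GazeRecording

__all__ = [
    "FrequencySeries",
    "blink_mask",
    "remove_blinks",
    "protocol_mask",
    "trim_to_protocol",
    "frequency_profile",
]


@dataclass
class FrequencySeries:
    """Across-subject per-second sample-rate summary.

    ``second_index[k]`` labels the half-open bin ``[k, k+1)`` seconds from
    each recording's own first timestamp; ``mean_hz`` / ``sd_hz`` are the
    across-subject mean and population standard deviation of the per-bin
    sample counts.  ``per_subject`` keeps the raw (subject x bin) counts.
    """

    second_index: np.ndarray
    mean_hz: np.ndarray
    sd_hz: np.ndarray
    per_subject: np.ndarray

    def __post_init__(self) -> None:
        if not (self.second_index.shape == self.mean_hz.shape == self.sd_hz.shape):
            raise ValueError("second_index, mean_hz and sd_hz must align")
        if self.mean_hz.size and np.min(self.mean_hz) < 0:
            raise ValueError("mean_hz must be non-negative")


def blink_mask(recording: GazeRecording, cutoff: float = 0.75) -> np.ndarray:
    """Boolean keep-mask: True for samples below the blink cutoff in both eyes."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"blink cutoff must lie in (0, 1), got {cutoff}")
    # strict ">": a coefficient exactly at the cutoff is retained
    return ~((recording.left_blink > cutoff) | (recording.right_blink > cutoff))


def remove_blinks(
    recording: GazeRecording, cutoff: float = 0.75
) -> Tuple[GazeRecording, float]:
    """Drop blink samples; return the filtered recording and removed fraction.

    A sample is a blink when either eye's eyelid coefficient is strictly
    above ``cutoff``.  Order is preserved; an empty recording yields an
    empty result with fraction 0.
    """
    keep = blink_mask(recording, cutoff)
    n = len(recording)
    frac = 0.0 if n == 0 else float(np.count_nonzero(~keep)) / n
    return recording.select(keep), frac


def protocol_mask(recording: GazeRecording, events) -> np.ndarray:
    """Boolean keep-mask for samples within [first t_on, last t_off] (closed)."""
    events = list(events)
    if not events:
        raise ValueError("cannot trim to an empty event log")
    t0 = min(e.t_on for e in events)
    t1 = max(e.t_off for e in events)
    return (recording.t >= t0) & (recording.t <= t1)


def trim_to_protocol(recording: GazeRecording, events) -> GazeRecording:
    """Keep only samples recorded between the first and last lit squares.

    The span is the closed interval [min t_on, max t_off] over the AoI
    event log; everything outside (free exploration lead-in, trailing
    samples) is discarded.
    """
    return recording.select(protocol_mask(recording, events))


def frequency_profile(recordings: Sequence[GazeRecording]) -> FrequencySeries:
    """Per-second acquisition-rate profile averaged across subjects.

    Each recording is binned into half-open 1-second bins from its own
    first timestamp; the series reports the across-subject mean and
    population SD of the per-bin counts.  Subjects shorter than the longest
    session contribute zero counts to the trailing bins.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("frequency_profile requires at least one recording")
    counts = []
    n_bins = 0
    for rec in recordings:
        if len(rec) == 0:
            counts.append(np.zeros(0, dtype=int))
            continue
        offsets = np.floor(rec.t - rec.t[0]).astype(int)
        c = np.bincount(offsets)
        counts.append(c)
        n_bins = max(n_bins, c.size)
    mat = np.zeros((len(counts), n_bins), dtype=float)
    for i, c in enumerate(counts):
        mat[i, : c.size] = c
    return FrequencySeries(
        second_index=np.arange(n_bins),
        mean_hz=mat.mean(axis=0) if n_bins else np.zeros(0),
        sd_hz=mat.std(axis=0) if n_bins else np.zeros(0),  # population SD
        per_subject=mat,
    )
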