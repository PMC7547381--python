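"""Synthetic VR gaze sessions with ground-truth fixation labels.

The generator replays a guided two-panel protocol: the viewer stands in
front of a 4x4 number panel (squares 1-16, frontal, spanning roughly -15 to
+15 degrees of azimuth) with a second 4x4 panel (squares 17-32) placed to
the right (about 25-45 degrees), so that following the lit squares forces
head movement.  Fifteen squares light up for 3 s each in a fixed sequence,
preceded by a free-exploration lead-in.  Every lit square is an AoI.

Simulated streams emulate an HMD eye tracker driven by the render loop:
~45 Hz mean effective rate with jittered intervals and occasional dropouts,
fixation/saccade alternation locked to the lit sequence, bounded angular
jitter around the fixated target, eyelid-coefficient blink episodes, and a
slow smooth head trajectory.  Every sample carries a ground-truth class
(fixation / saccade / blink / free) and the generating AoI, so detection
and feature code can be validated without recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .features import AoIEvent, AoIRegion
from .gaze_model import GazeRecording

__all__ = [
    "ProtocolSpec",
    "SimParams",
    "SimulatedSession",
    "default_protocol",
    "simulate_session",
    "simulate_cohort",
    "LIT_SEQUENCE",
]

# Guided lit-square order of the two-panel task.
LIT_SEQUENCE: Tuple[int, ...] = (1, 16, 4, 13, 6, 11, 7, 10, 17, 32, 22, 10, 20, 5, 30)

# Horizontal angular extents of the two panels as seen from the viewer.
_FRONT_HALF_DEG = 14.93
_SIDE_MIN_DEG = 25.02
_SIDE_MAX_DEG = 45.00
_FRONT_DISTANCE = 2.5  # meters, viewer to frontal panel plane
_EYE_HEIGHT = 1.6  # meters

# Within-fixation gaze wander is the sum of a slow bounded drift and fast
# per-sample jitter, both scaled by the noise SD.  The radial budget is
# capped at 1.4 x SD (drift <= 0.75 x SD, jitter clipped at 0.65 x SD), so a
# labeled fixation's pairwise dispersion stays below ~2.8 x SD and the
# ground-truth segments remain self-consistent with the classifier's
# invariants for thresholds >= 3 x SD.
_DRIFT_AMP = 0.53  # per-component drift amplitude, x SD (radial <= 0.75 x SD)
_JITTER_SD = 0.45  # per-component jitter SD, x SD
_JITTER_CLIP = 0.65  # radial jitter cap, x SD

# Saccades land with a terminal snap rather than an asymptotic glide:
# in-flight samples whose angular distance to either endpoint (seen from the
# sample's own head) is below this multiple of the noise SD are placed
# exactly on that endpoint.  The capture radius exceeds the noise cone's
# 3 x SD dispersion budget plus its 1.4 x SD radial half-width, so an
# unsnapped in-flight sample can never sit within one cone-width of a
# fixation cluster -- it is either exactly at an endpoint or clearly
# outside any plausible fixation cone.
_SACCADE_SNAP = 5.5

_UP = np.array([0.0, 1.0, 0.0])


def _angle_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise angle (radians) between two bundles of 3-vectors."""
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    cos = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300)
    return np.arccos(np.clip(cos, -1.0, 1.0))


@dataclass(frozen=True)
class ProtocolSpec:
    """Panel geometry, lit sequence and timing of a guided session."""

    regions: Tuple[AoIRegion, ...]
    sequence: Tuple[int, ...]
    lit_duration: float = 3.0
    lead_in: float = 60.0
    viewer: np.ndarray = field(
        default_factory=lambda: np.array([0.0, _EYE_HEIGHT, 0.0])
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "viewer", np.asarray(self.viewer, dtype=float))
        ids = {r.aoi_id for r in self.regions}
        missing = set(self.sequence) - ids
        if missing:
            raise ValueError(f"sequence references unknown AoI ids {sorted(missing)}")
        if not (self.lit_duration > 0):
            raise ValueError("lit_duration must be positive")
        if self.lead_in < 0:
            raise ValueError("lead_in must be non-negative")

    @property
    def region_by_id(self) -> dict:
        return {r.aoi_id: r for r in self.regions}

    @property
    def guided_duration(self) -> float:
        """Total lit time of the guided task, seconds."""
        return self.lit_duration * len(self.sequence)

    def events(self) -> List[AoIEvent]:
        """Consecutive lit intervals, starting right after the lead-in."""
        out = []
        for k, aoi_id in enumerate(self.sequence):
            t_on = self.lead_in + k * self.lit_duration
            out.append(AoIEvent(aoi_id=aoi_id, t_on=t_on, t_off=t_on + self.lit_duration))
        return out


def _panel_regions(
    first_id: int,
    center: np.ndarray,
    u_axis: np.ndarray,
    half_width: float,
) -> List[AoIRegion]:
    """4x4 grid of square AoIs, numbered row-major from the top-left."""
    cell = half_width / 2.0  # full cell size for a 4-cell span of 2*half_width
    regions = []
    for row in range(4):
        for col in range(4):
            offset_u = (-1.5 + col) * cell
            offset_v = (1.5 - row) * cell
            regions.append(
                AoIRegion(
                    aoi_id=first_id + row * 4 + col,
                    center=center + offset_u * u_axis + offset_v * _UP,
                    edge_u=u_axis * (cell / 2.0),
                    edge_v=_UP * (cell / 2.0),
                )
            )
    return regions


def default_protocol(lead_in: float = 60.0) -> ProtocolSpec:
    """The two-panel guided protocol with the standard lit sequence.

    The frontal panel is placed so its horizontal extent spans +/-14.93
    degrees of azimuth from the default viewer position; the second panel,
    of the same physical size, is rotated to span 25.02-45.00 degrees to
    the right.  Squares are lit for 3 s each; the free-exploration lead-in
    defaults to 60 s.
    """
    viewer = np.array([0.0, _EYE_HEIGHT, 0.0])
    half_width = _FRONT_DISTANCE * math.tan(math.radians(_FRONT_HALF_DEG))
    front_center = viewer + np.array([0.0, 0.0, _FRONT_DISTANCE])
    front = _panel_regions(1, front_center, np.array([1.0, 0.0, 0.0]), half_width)

    phi_c = math.radians(0.5 * (_SIDE_MIN_DEG + _SIDE_MAX_DEG))
    alpha = math.radians(0.5 * (_SIDE_MAX_DEG - _SIDE_MIN_DEG))
    side_distance = half_width / math.tan(alpha)
    side_dir = np.array([math.sin(phi_c), 0.0, math.cos(phi_c)])
    side_u = np.array([math.cos(phi_c), 0.0, -math.sin(phi_c)])
    side_center = viewer + side_distance * side_dir
    side = _panel_regions(17, side_center, side_u, half_width)

    return ProtocolSpec(
        regions=tuple(front + side),
        sequence=LIT_SEQUENCE,
        lit_duration=3.0,
        lead_in=lead_in,
        viewer=viewer,
    )


@dataclass(frozen=True)
class SimParams:
    """Stream-generation parameters emulating an HMD eye tracker.

    Rates are per minute where noted; angles in degrees; times in seconds.
    """

    rate_hz: float = 45.0  # nominal effective sampling rate
    jitter_sd: float = 0.002  # SD of the inter-sample interval, s
    noise_sd_deg: float = 0.3  # within-fixation angular wander scale (drift + jitter)
    saccade_duration: float = 0.05  # gaze travel time between targets
    blink_rate_per_min: float = 4.0  # blink episodes per minute
    blink_duration: float = 0.12  # eyelid-closure episode length, s
    dropout_rate_per_min: float = 0.1  # render-stall dropouts per minute
    dropout_length: float = 0.3  # samples deleted per dropout, s
    head_amplitude: float = 0.05  # head sway amplitude, m
    adherence: float = 0.95  # P(subject fixates the lit square)
    tail: float = 0.5  # extra recording after the last event, s

    def __post_init__(self) -> None:
        if not (self.rate_hz > 0):
            raise ValueError("rate_hz must be positive")
        if not (0.0 <= self.adherence <= 1.0):
            raise ValueError("adherence must lie in [0, 1]")
        for name in (
            "jitter_sd",
            "noise_sd_deg",
            "saccade_duration",
            "blink_rate_per_min",
            "blink_duration",
            "dropout_rate_per_min",
            "dropout_length",
            "head_amplitude",
            "tail",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulatedSession:
    """A simulated stream plus its event log and per-sample ground truth.

    ``labels`` is row-aligned with ``recording`` and carries ``cls`` in
    {fixation, saccade, blink, free}, ``target_aoi`` (the square the gaze
    was generated toward) and ``lit_aoi`` (the concurrently lit square, -1
    outside the guided task).
    """

    recording: GazeRecording
    events: List[AoIEvent]
    labels: pd.DataFrame
    protocol: ProtocolSpec


def _head_trajectory(t: np.ndarray, base: np.ndarray, amp: float, rng) -> np.ndarray:
    """Slow smooth sway around the viewer position."""
    freqs = rng.uniform(0.03, 0.10, size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    sway = np.stack(
        [
            np.sin(2.0 * np.pi * freqs[0] * t + phases[0]),
            0.3 * np.sin(2.0 * np.pi * freqs[1] * t + phases[1]),
            np.sin(2.0 * np.pi * freqs[2] * t + phases[2]),
        ],
        axis=1,
    )
    return base[None, :] + amp * sway


def _perturbed_gaze(
    heads: np.ndarray,
    ts: np.ndarray,
    t0: float,
    region: AoIRegion,
    sd_deg: float,
    rng,
) -> np.ndarray:
    """Gaze impact points wandering around a region's center in its plane.

    The angular wander is the sum of a slow smooth drift (a per-dwell
    sinusoid in the two in-plane components, amplitude ``_DRIFT_AMP`` x SD
    each) and fast per-sample Gaussian jitter (``_JITTER_SD`` x SD per
    component, radially clipped at ``_JITTER_CLIP`` x SD).  The offsets are
    laid out directly in the panel plane, scaled by the per-sample viewing
    distance, so the angular spread subtended at the head is bounded by the
    radial budget regardless of how obliquely the panel is viewed.
    """
    m = heads.shape[0]
    center = region.center
    if sd_deg <= 0:
        return np.tile(center, (m, 1))
    sd = math.radians(sd_deg)
    freqs = rng.uniform(0.25, 0.7, size=2)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    rel = ts - t0
    drift = _DRIFT_AMP * sd * np.stack(
        [
            np.sin(2.0 * np.pi * freqs[0] * rel + phases[0]),
            np.sin(2.0 * np.pi * freqs[1] * rel + phases[1]),
        ],
        axis=1,
    )
    jitter = rng.normal(0.0, _JITTER_SD * sd, size=(m, 2))
    r = np.linalg.norm(jitter, axis=1)
    cap = _JITTER_CLIP * sd
    scale = np.where(r > cap, cap / np.maximum(r, 1e-300), 1.0)
    eps = drift + jitter * scale[:, None]
    dist = np.linalg.norm(center[None, :] - heads, axis=1)
    u_hat = region.edge_u / np.linalg.norm(region.edge_u)
    v_hat = region.edge_v / np.linalg.norm(region.edge_v)
    offsets = (dist * eps[:, 0])[:, None] * u_hat + (dist * eps[:, 1])[:, None] * v_hat
    return center[None, :] + offsets


def _build_segments(
    protocol: ProtocolSpec, params: SimParams, rng, t_end: float
) -> List[Tuple[float, float, str, int, int, int]]:
    """Piecewise gaze script: (t0, t1, kind, from_id, to_id, lit_id).

    ``kind`` is 'sacc' / 'fix' for guided gaze shifts and dwells, and
    'free' / 'free_dwell' for their lead-in or tail counterparts;
    ``lit_id`` is the concurrently lit square or -1.
    """
    ids = [r.aoi_id for r in protocol.regions]
    segs: List[Tuple[float, float, str, int, int, int]] = []
    sd = params.saccade_duration
    current = int(rng.choice(ids))
    tcur = 0.0
    # free-exploration lead-in: wander square to square
    while tcur < protocol.lead_in - 1e-12:
        nxt = int(rng.choice([i for i in ids if i != current]))
        s_end = min(tcur + sd, protocol.lead_in)
        if s_end > tcur:
            segs.append((tcur, s_end, "free", current, nxt, -1))
        dwell_end = min(s_end + rng.uniform(0.4, 1.0), protocol.lead_in)
        if dwell_end > s_end:
            segs.append((s_end, dwell_end, "free_dwell", nxt, nxt, -1))
        current = nxt
        tcur = dwell_end
    # guided task: one saccade + one dwell per lit event
    for event in protocol.events():
        if params.adherence >= 1.0 or rng.random() < params.adherence:
            target = event.aoi_id
        else:
            # a distracted subject shifts to a new salient square -- neither
            # the lit one nor the one already being fixated
            target = int(rng.choice([i for i in ids if i not in (event.aoi_id, current)]))
        s_end = min(event.t_on + sd, event.t_off)
        if s_end > event.t_on:
            segs.append((event.t_on, s_end, "sacc", current, target, event.aoi_id))
        segs.append((s_end, event.t_off, "fix", target, target, event.aoi_id))
        current = target
    if t_end > segs[-1][1]:
        segs.append((segs[-1][1], t_end, "free_dwell", current, current, -1))
    return segs


def simulate_session(
    protocol: Optional[ProtocolSpec] = None,
    params: Optional[SimParams] = None,
    seed=0,
    subject_id: str = "S00",
) -> SimulatedSession:
    """Generate one subject's gaze stream with ground-truth labels.

    The same seed reproduces the session bit for bit.  Blink episodes are
    coupled to gaze shifts (eyelid closures preferentially accompany
    saccades), so an episode raises the eyelid coefficients above the blink
    cutoff for its duration starting at a randomly chosen gaze-shift onset.
    Dropouts delete contiguous runs of samples, emulating render stalls.
    """
    protocol = protocol or default_protocol()
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    if params.saccade_duration >= protocol.lit_duration:
        raise ValueError("saccade_duration must be shorter than lit_duration")

    events = protocol.events()
    t_end = events[-1].t_off + params.tail

    # jittered timestamps
    n_guess = int(math.ceil(t_end * params.rate_hz * 1.2)) + 50
    dts = 1.0 / params.rate_hz + rng.normal(0.0, params.jitter_sd, size=n_guess)
    dts = np.maximum(dts, 1e-3)
    t = np.concatenate([[0.0], np.cumsum(dts)])
    t = t[t < t_end]
    n = t.size

    head = _head_trajectory(t, protocol.viewer, params.head_amplitude, rng)
    segs = _build_segments(protocol, params, rng, t_end)
    seg_starts = np.array([s[0] for s in segs])
    seg_idx = np.clip(np.searchsorted(seg_starts, t, side="right") - 1, 0, len(segs) - 1)

    gaze = np.zeros((n, 3))
    cls = np.empty(n, dtype=object)
    target_aoi = np.full(n, -1, dtype=int)
    lit_aoi = np.full(n, -1, dtype=int)
    by_id = protocol.region_by_id
    for s, (t0, t1, kind, from_id, to_id, lit) in enumerate(segs):
        sel = np.nonzero(seg_idx == s)[0]
        if sel.size == 0:
            continue
        ts = t[sel]
        if kind in ("fix", "free_dwell"):
            gaze[sel] = _perturbed_gaze(
                head[sel], ts, t0, by_id[to_id], params.noise_sd_deg, rng
            )
            cls[sel] = "fixation" if kind == "fix" else "free"
        else:  # saccade: gaze travels between the two centers
            frac = (ts - t0) / (t1 - t0)
            # steep sigmoid position profile (peak velocity mid-flight), so
            # in-flight samples cluster near the endpoints as in real saccades
            frac = frac * frac * frac * (frac * (6.0 * frac - 15.0) + 10.0)
            frac = frac * frac * frac * (frac * (6.0 * frac - 15.0) + 10.0)
            p_from = by_id[from_id].center
            p_to = by_id[to_id].center
            raw = (1.0 - frac)[:, None] * p_from + frac[:, None] * p_to
            if params.noise_sd_deg > 0:
                # angular endpoint capture (see _SACCADE_SNAP)
                snap_rad = _SACCADE_SNAP * math.radians(params.noise_sd_deg)
                hs = head[sel]
                ang_from = _angle_between(raw - hs, p_from[None, :] - hs)
                ang_to = _angle_between(raw - hs, p_to[None, :] - hs)
                raw = np.where(
                    ((ang_to <= ang_from) & (ang_to < snap_rad))[:, None], p_to, raw
                )
                raw = np.where(
                    ((ang_from < ang_to) & (ang_from < snap_rad))[:, None], p_from, raw
                )
            gaze[sel] = raw
            cls[sel] = "saccade" if kind == "sacc" else "free"
        target_aoi[sel] = to_id
        lit_aoi[sel] = lit

    left = rng.uniform(0.0, 0.3, size=n)
    right = rng.uniform(0.0, 0.3, size=n)

    # blink episodes, coupled to gaze-shift onsets
    if params.blink_rate_per_min > 0 and params.blink_duration > 0:
        n_blinks = rng.poisson(params.blink_rate_per_min * t_end / 60.0)
        onsets = [s[0] for s in segs if s[2] in ("sacc", "free")]
        if onsets and n_blinks > 0:
            chosen = rng.choice(len(onsets), size=min(n_blinks, len(onsets)), replace=False)
            for c in np.sort(chosen):
                t0 = onsets[c]
                sel = (t >= t0) & (t < t0 + params.blink_duration)
                left[sel] = rng.uniform(0.8, 0.995, size=int(sel.sum()))
                right[sel] = rng.uniform(0.8, 0.995, size=int(sel.sum()))
                cls[sel] = "blink"

    # dropouts: delete contiguous runs
    keep = np.ones(n, dtype=bool)
    if params.dropout_rate_per_min > 0 and params.dropout_length > 0:
        n_drop = rng.poisson(params.dropout_rate_per_min * t_end / 60.0)
        for _ in range(n_drop):
            s0 = rng.uniform(0.0, max(t_end - params.dropout_length, 0.0))
            keep &= ~((t >= s0) & (t < s0 + params.dropout_length))

    recording = GazeRecording(
        subject_id=subject_id,
        t=t[keep],
        gaze=gaze[keep],
        head=head[keep],
        left_blink=left[keep],
        right_blink=right[keep],
    )
    labels = pd.DataFrame(
        {
            "cls": cls[keep],
            "target_aoi": target_aoi[keep],
            "lit_aoi": lit_aoi[keep],
        }
    ).reset_index(drop=True)
    return SimulatedSession(
        recording=recording, events=events, labels=labels, protocol=protocol
    )


def simulate_cohort(
    n_subjects: int = 10,
    protocol: Optional[ProtocolSpec] = None,
    params: Optional[SimParams] = None,
    seed=0,
) -> List[SimulatedSession]:
    """Independent per-subject sessions from one master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocol = protocol or default_protocol()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        simulate_session(protocol, params, seed=child, subject_id=f"S{i:02d}")
        for i, child in enumerate(children)
    ]
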