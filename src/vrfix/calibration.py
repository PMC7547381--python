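"""Grid search and rule-based selection of I-DT thresholds.

The classifier's two thresholds -- angular dispersion and minimum time
window -- are calibrated by evaluating four cohort features on a parameter
grid and intersecting per-feature acceptance rules:

* number of fixations: acceptable strictly *after* the row-wise maximum
  (the region before and at the peak is unstable);
* percentage of classified points: its elbow coincides with the fixation
  count maximum, and the feature should be as high as possible -- it picks
  the optimum inside the acceptable region rather than bounding it;
* mean fixation time: acceptable strictly below a predefined ceiling
  (default 1.5 s);
* percentage of fixations inside lit AoIs: acceptable where the smoothed
  curve is *stable*, i.e. the absolute first difference along the
  dispersion axis (after a 3-point moving average) stays below 2
  percentage points per grid step.

Calibration proceeds in two phases: phase 1 intersects the AoI-free rules
and maximises the percentage of classified points; phase 2 adds the AoI
stability rule and re-selects.  Phase 1 therefore applies to free-viewing
tasks as well; phase 2 requires a guided protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import AoIEvent, AoIRegion, mean_fix_time, n_fixations, pct_in_aoi, pct_points
from .gaze_model import GazeRecording, IDTParams
from .idt import detect_fixations

__all__ = [
    "NoAcceptableRegionError",
    "ParameterGrid",
    "default_grid",
    "FeatureSurface",
    "CalibrationConfig",
    "OptimumCell",
    "CalibrationResult",
    "build_surfaces",
    "sma3",
    "stability_mask",
    "rule_after_peak",
    "rule_elbow",
    "rule_mean_time",
    "select_optimum",
    "calibrate",
]

FEATURE_NAMES = ("n_fixations", "pct_points", "mean_fix_time", "pct_in_aoi")


class NoAcceptableRegionError(RuntimeError):
    """No grid cell satisfies every calibration rule."""


@dataclass(frozen=True)
class ParameterGrid:
    """Dispersion-threshold (degrees) x time-window (seconds) search grid."""

    dispersion: np.ndarray
    window: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dispersion", "window"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"{name} values must form a non-empty 1-D array")
            if np.any(v <= 0):
                raise ValueError(f"{name} values must be strictly positive")
            if v.size > 1 and np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} values must be strictly increasing")
            object.__setattr__(self, name, v)

    @property
    def shape(self) -> Tuple[int, int]:
        """(n_windows, n_dispersions) -- the orientation of every surface."""
        return (self.window.size, self.dispersion.size)


def default_grid() -> ParameterGrid:
    """Dispersion 0.1-2.5 deg in 0.1 deg steps, windows 0.10-0.50 s in 0.05 s
    steps.

    The nominal 0 deg endpoint of the dispersion sweep is dropped: a zero
    threshold admits no fixation and leaves every feature undefined.
    """
    return ParameterGrid(
        dispersion=np.round(np.arange(1, 26) * 0.1, 10),
        window=np.round(0.10 + 0.05 * np.arange(9), 10),
    )


@dataclass(frozen=True)
class FeatureSurface:
    """One feature evaluated over the grid, averaged across subjects.

    ``values[i, j]`` corresponds to ``grid.window[i]`` and
    ``grid.dispersion[j]``.
    """

    name: str
    grid: ParameterGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(
                f"surface shape {v.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("surface contains non-finite cells")
        object.__setattr__(self, "values", v)


@dataclass
class CalibrationConfig:
    """Tunable thresholds of the calibration procedure (units in names)."""

    t_max: float = 1.5  # mean-fixation-time ceiling, seconds
    stability_cutoff: float = 2.0  # pct-points per grid step
    freq_floor: float = 30.0  # Hz
    blink_cutoff: float = 0.75
    plane_tol: float = 0.05  # meters, AoI in-plane tolerance
    dispersion_start: float = 0.1
    dispersion_stop: float = 2.5
    dispersion_step: float = 0.1
    window_start: float = 0.10
    window_stop: float = 0.50
    window_step: float = 0.05

    def grid(self) -> ParameterGrid:
        nd = int(round((self.dispersion_stop - self.dispersion_start) / self.dispersion_step)) + 1
        nw = int(round((self.window_stop - self.window_start) / self.window_step)) + 1
        return ParameterGrid(
            dispersion=np.round(self.dispersion_start + self.dispersion_step * np.arange(nd), 10),
            window=np.round(self.window_start + self.window_step * np.arange(nw), 10),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "CalibrationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def build_surfaces(
    recordings: Sequence[GazeRecording],
    events: Sequence[AoIEvent],
    regions: Sequence[AoIRegion],
    grid: Optional[ParameterGrid] = None,
    *,
    freq_floor: float = 30.0,
    blink_cutoff: float = 0.75,
    plane_tol: float = 0.05,
) -> Dict[str, FeatureSurface]:
    """Evaluate the four features on every grid cell.

    Runs the fixation classifier per cell per subject on the (already
    preprocessed) recordings and aggregates the across-subject means.
    Returns a dict keyed by feature name.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("build_surfaces requires at least one recording")
    if grid is None:
        grid = default_grid()
    values = {name: np.zeros(grid.shape) for name in FEATURE_NAMES}
    for i, w in enumerate(grid.window):
        for j, d in enumerate(grid.dispersion):
            params = IDTParams(
                dispersion_th=float(d),
                time_window=float(w),
                freq_floor=freq_floor,
                blink_cutoff=blink_cutoff,
            )
            try:
                fx = [detect_fixations(rec, params) for rec in recordings]
            except Exception as exc:  # re-raise with grid-cell context
                raise RuntimeError(
                    f"fixation detection failed at dispersion {d} deg, window {w} s"
                ) from exc
            values["n_fixations"][i, j] = n_fixations(fx)
            values["pct_points"][i, j] = pct_points(recordings, fx)
            values["mean_fix_time"][i, j] = mean_fix_time(fx)
            values["pct_in_aoi"][i, j] = pct_in_aoi(fx, events, regions, plane_tol)
    return {name: FeatureSurface(name, grid, values[name]) for name in FEATURE_NAMES}


def sma3(series) -> np.ndarray:
    """Centered 3-point simple moving average; shrinks to the 2 available
    points at each edge."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("sma3 expects a 1-D series")
    if x.size <= 2:
        return x.copy()
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def stability_mask(surface: FeatureSurface, cutoff: float = 2.0) -> np.ndarray:
    """Cells where the AoI-percentage curve is locally stable.

    Per window row the curve is smoothed with :func:`sma3` along the
    dispersion axis, and forward differences are taken; a cell is stable
    iff the absolute difference starting at it is below ``cutoff``
    (percentage points per grid step).  The last cell of a row, which has
    no forward difference, inherits the preceding one.
    """
    vals = surface.values
    mask = np.zeros(vals.shape, dtype=bool)
    for i in range(vals.shape[0]):
        row = sma3(vals[i])
        if row.size == 1:
            mask[i, 0] = True
            continue
        d = np.abs(np.diff(row))
        mask[i, :-1] = d < cutoff
        mask[i, -1] = d[-1] < cutoff
    return mask


def rule_after_peak(surface: FeatureSurface) -> np.ndarray:
    """Cells strictly after the row-wise maximum of the fixation count.

    Ties in the maximum resolve to the first (smallest-dispersion) peak.
    """
    vals = surface.values
    mask = np.zeros(vals.shape, dtype=bool)
    for i in range(vals.shape[0]):
        peak = int(np.argmax(vals[i]))
        mask[i, peak + 1 :] = True
    return mask


def rule_elbow(surface: FeatureSurface) -> np.ndarray:
    """Cells after the elbow of the classified-points curve.

    The elbow coincides with the fixation-count maximum of the same window
    row, so this rule is evaluated on the ``n_fixations`` surface and is
    numerically identical to :func:`rule_after_peak`; it is kept as a
    separately named rule for reporting.
    """
    return rule_after_peak(surface)


def rule_mean_time(surface: FeatureSurface, t_max: float = 1.5) -> np.ndarray:
    """Cells whose mean fixation time is strictly below ``t_max`` seconds."""
    return surface.values < t_max


@dataclass(frozen=True)
class OptimumCell:
    """A selected grid cell with its parameter values."""

    dispersion_th: float
    time_window: float
    window_index: int
    dispersion_index: int
    pct_points: float

    def to_dict(self) -> dict:
        return {
            "dispersion_th": self.dispersion_th,
            "time_window": self.time_window,
            "pct_points": self.pct_points,
        }


def select_optimum(
    mask: np.ndarray, pct_points_surface: FeatureSurface
) -> OptimumCell:
    """Among acceptable cells, the one maximising the classified-point
    percentage; ties break toward smaller dispersion, then smaller window."""
    grid = pct_points_surface.grid
    vals = pct_points_surface.values
    if mask.shape != vals.shape:
        raise ValueError("mask and surface shapes differ")
    cells = np.argwhere(mask)
    if cells.size == 0:
        raise NoAcceptableRegionError("no grid cell satisfies all calibration rules")
    best = min(
        (tuple(c) for c in cells),
        key=lambda c: (-vals[c], grid.dispersion[c[1]], grid.window[c[0]]),
    )
    i, j = best
    return OptimumCell(
        dispersion_th=float(grid.dispersion[j]),
        time_window=float(grid.window[i]),
        window_index=int(i),
        dispersion_index=int(j),
        pct_points=float(vals[i, j]),
    )


def _intervals(mask_row: np.ndarray, axis_values: np.ndarray) -> List[List[float]]:
    """Contiguous True runs of a row as [lo, hi] value intervals."""
    out: List[List[float]] = []
    start = None
    for idx, flag in enumerate(mask_row):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            out.append([float(axis_values[start]), float(axis_values[idx - 1])])
            start = None
    if start is not None:
        out.append([float(axis_values[start]), float(axis_values[-1])])
    return out


@dataclass
class CalibrationResult:
    """Outcome of the two-phase grid calibration."""

    grid: ParameterGrid
    surfaces: Dict[str, FeatureSurface]
    masks: Dict[str, np.ndarray]
    phase1_optimum: OptimumCell
    optimum: OptimumCell
    report: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.report, **kwargs)


def calibrate(
    recordings: Sequence[GazeRecording],
    events: Sequence[AoIEvent],
    regions: Sequence[AoIRegion],
    grid: Optional[ParameterGrid] = None,
    config: Optional[CalibrationConfig] = None,
    surfaces: Optional[Dict[str, FeatureSurface]] = None,
) -> CalibrationResult:
    """Run the four-step calibration strategy on a preprocessed cohort.

    Phase 1 evaluates the AoI-free rules (after-peak/elbow on the fixation
    count, mean-time ceiling) and selects the cell maximising the
    classified-point percentage.  Phase 2 adds the AoI stability rule to
    the combined mask and re-selects.  Both optima and the per-window
    acceptable dispersion intervals are reported.  Precomputed surfaces may
    be supplied to avoid re-running the grid search.
    """
    config = config or CalibrationConfig()
    if grid is None:
        grid = config.grid()
    if surfaces is None:
        surfaces = build_surfaces(
            recordings,
            events,
            regions,
            grid,
            freq_floor=config.freq_floor,
            blink_cutoff=config.blink_cutoff,
            plane_tol=config.plane_tol,
        )
    m_peak = rule_after_peak(surfaces["n_fixations"])
    m_elbow = rule_elbow(surfaces["n_fixations"])
    m_time = rule_mean_time(surfaces["mean_fix_time"], config.t_max)
    phase1 = m_peak & m_elbow & m_time
    phase1_opt = select_optimum(phase1, surfaces["pct_points"])
    m_stab = stability_mask(surfaces["pct_in_aoi"], config.stability_cutoff)
    phase2 = phase1 & m_stab
    opt = select_optimum(phase2, surfaces["pct_points"])
    masks = {
        "after_peak": m_peak,
        "elbow": m_elbow,
        "mean_time": m_time,
        "stability": m_stab,
        "phase1": phase1,
        "phase2": phase2,
    }
    report = {
        "windows_s": [float(w) for w in grid.window],
        "dispersion_deg": [float(d) for d in grid.dispersion],
        "phase1_intervals_deg": [
            _intervals(phase1[i], grid.dispersion) for i in range(grid.shape[0])
        ],
        "phase2_intervals_deg": [
            _intervals(phase2[i], grid.dispersion) for i in range(grid.shape[0])
        ],
        "phase1_optimum": phase1_opt.to_dict(),
        "optimum": opt.to_dict(),
        "config": config.to_dict(),
    }
    return CalibrationResult(
        grid=grid,
        surfaces=surfaces,
        masks=masks,
        phase1_optimum=phase1_opt,
        optimum=opt,
        report=report,
    )
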