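"""CSV/JSON serialization of gaze streams, events, regions and results.

The gaze dialect is a plain comma-separated file with a mandatory header
``t,gaze_x,gaze_y,gaze_z,head_x,head_y,head_z,left_blink,right_blink`` and
decimal-point floats.  Values round-trip at 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .features import AoIEvent, AoIRegion
from .gaze_model import Fixation, GazeRecording
from .preprocess import FrequencySeries

__all__ = [
    "GAZE_COLUMNS",
    "read_gaze",
    "write_gaze",
    "read_events",
    "write_events",
    "read_regions",
    "write_regions",
    "recording_from_frame",
    "write_fixations",
    "write_labels",
    "read_labels",
    "write_frequency",
    "surfaces_to_frame",
]

GAZE_COLUMNS = (
    "t",
    "gaze_x",
    "gaze_y",
    "gaze_z",
    "head_x",
    "head_y",
    "head_z",
    "left_blink",
    "right_blink",
)

_FLOAT_FMT = "%.9g"


def recording_from_frame(
    df: pd.DataFrame, column_map: dict | None = None, subject_id: str = "subject"
) -> GazeRecording:
    """Build a recording from a vendor-exported table.

    Vendor log layouts (engine/SDK exports) are undocumented and vary, so
    no parser for them is shipped; instead, load the export yourself (e.g.
    ``pd.read_csv``) and pass ``column_map`` mapping *vendor* column names
    to the dialect names in :data:`GAZE_COLUMNS`.  Columns already named
    per the dialect need no entry.
    """
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mapped frame is missing columns {missing}")
    return GazeRecording(
        subject_id=subject_id,
        t=df["t"].to_numpy(dtype=float),
        gaze=df[["gaze_x", "gaze_y", "gaze_z"]].to_numpy(dtype=float),
        head=df[["head_x", "head_y", "head_z"]].to_numpy(dtype=float),
        left_blink=df["left_blink"].to_numpy(dtype=float),
        right_blink=df["right_blink"].to_numpy(dtype=float),
    )


def read_gaze(path, subject_id: str | None = None) -> GazeRecording:
    """Read a gaze CSV with strict schema validation.

    Errors name the offending data line (header is line 1): non-monotone
    timestamps, missing columns and out-of-range blink coefficients are all
    rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(bad[0]) + 3  # +1 header, +1 one-based, +1 second sample
            raise ValueError(
                f"{path}: timestamps not strictly increasing at line {line}"
            )
    for col in ("left_blink", "right_blink"):
        vals = df[col].to_numpy(dtype=float)
        out = np.nonzero((vals < 0.0) | (vals > 1.0))[0]
        if out.size:
            line = int(out[0]) + 2
            raise ValueError(
                f"{path}: {col} outside [0, 1] at line {line} (value {vals[out[0]]})"
            )
    return GazeRecording(
        subject_id=subject_id or path.stem,
        t=t,
        gaze=df[["gaze_x", "gaze_y", "gaze_z"]].to_numpy(dtype=float),
        head=df[["head_x", "head_y", "head_z"]].to_numpy(dtype=float),
        left_blink=df["left_blink"].to_numpy(dtype=float),
        right_blink=df["right_blink"].to_numpy(dtype=float),
    )


def write_gaze(recording: GazeRecording, path) -> None:
    df = pd.DataFrame(
        {
            "t": recording.t,
            "gaze_x": recording.gaze[:, 0],
            "gaze_y": recording.gaze[:, 1],
            "gaze_z": recording.gaze[:, 2],
            "head_x": recording.head[:, 0],
            "head_y": recording.head[:, 1],
            "head_z": recording.head[:, 2],
            "left_blink": recording.left_blink,
            "right_blink": recording.right_blink,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> List[AoIEvent]:
    df = pd.read_csv(path)
    required = {"aoi_id", "t_on", "t_off"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        AoIEvent(aoi_id=int(r.aoi_id), t_on=float(r.t_on), t_off=float(r.t_off))
        for r in df.itertuples()
    ]


def write_events(events: Sequence[AoIEvent], path) -> None:
    pd.DataFrame(
        {
            "aoi_id": [e.aoi_id for e in events],
            "t_on": [e.t_on for e in events],
            "t_off": [e.t_off for e in events],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_regions(path) -> List[AoIRegion]:
    data = json.loads(Path(path).read_text())
    return [
        AoIRegion(
            aoi_id=int(r["aoi_id"]),
            center=np.asarray(r["center"], dtype=float),
            edge_u=np.asarray(r["edge_u"], dtype=float),
            edge_v=np.asarray(r["edge_v"], dtype=float),
        )
        for r in data
    ]


def write_regions(regions: Sequence[AoIRegion], path) -> None:
    data = [
        {
            "aoi_id": r.aoi_id,
            "center": [float(x) for x in r.center],
            "edge_u": [float(x) for x in r.edge_u],
            "edge_v": [float(x) for x in r.edge_v],
        }
        for r in regions
    ]
    Path(path).write_text(json.dumps(data, indent=2))


def write_fixations(subject_id: str, fixations: Sequence[Fixation], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [subject_id] * len(fixations),
            "t_start": [f.t_start for f in fixations],
            "t_end": [f.t_end for f in fixations],
            "duration": [f.duration for f in fixations],
            "n_samples": [f.n_samples for f in fixations],
            "centroid_x": [f.centroid[0] for f in fixations],
            "centroid_y": [f.centroid[1] for f in fixations],
            "centroid_z": [f.centroid[2] for f in fixations],
            "head_x": [f.head_mean[0] for f in fixations],
            "head_y": [f.head_mean[1] for f in fixations],
            "head_z": [f.head_mean[2] for f in fixations],
            "dispersion_deg": [f.dispersion for f in fixations],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index_label="sample")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")


def write_frequency(series: FrequencySeries, path) -> None:
    pd.DataFrame(
        {
            "second": series.second_index,
            "mean_hz": series.mean_hz,
            "sd_hz": series.sd_hz,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def surfaces_to_frame(surfaces: dict) -> pd.DataFrame:
    """Long-format feature table keyed by (time_window, dispersion_th)."""
    any_surface = next(iter(surfaces.values()))
    grid = any_surface.grid
    rows = []
    for i, w in enumerate(grid.window):
        for j, d in enumerate(grid.dispersion):
            row = {"time_window": float(w), "dispersion_th": float(d)}
            for name, surf in surfaces.items():
                row[name] = float(surf.values[i, j])
            rows.append(row)
    return pd.DataFrame(rows)
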