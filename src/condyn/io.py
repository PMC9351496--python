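"""Tabular I/O: tracking tables, localization tables, reports.

Tracking tables are delimited text with one row per detection
(track id, frame, x, y); the column names and units of third-party
exports (e.g. TrackMate spot tables) are adapted through a
``ColumnMapping``.  Internally trajectories are in micrometres and
localization maps in nanometres; unit conversion happens only here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .spt import MIN_TRACK_FRAMES, Trajectory

__all__ = [
    "ColumnMapping",
    "read_tracks",
    "write_tracks",
    "read_localizations",
    "write_localizations",
    "write_report",
    "write_trace_csv",
]

logger = logging.getLogger("condyn")

_UNIT_TO_UM = {"um": 1.0, "nm": 1e-3}
_UNIT_TO_NM = {"um": 1e3, "nm": 1.0}


@dataclass(frozen=True)
class ColumnMapping:
    """Maps source column names and units onto the internal schema."""

    track_id: str = "track_id"
    frame: str = "frame"
    x: str = "x_um"
    y: str = "y_um"
    unit: str = "um"
    frame_interval: float = 0.015  # s

    def __post_init__(self) -> None:
        if self.unit not in _UNIT_TO_UM:
            raise ValueError("unit must be 'um' or 'nm'")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in required:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"{path.name}: non-numeric value in column '{col}' (file row {row})"
            ) from exc
    return df


def read_tracks(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    min_frames: int = MIN_TRACK_FRAMES,
) -> list[Trajectory]:
    """Read a tracking table into trajectories (coordinates in um).

    Tracks shorter than ``min_frames`` detections are dropped (the
    conventional filter keeps tracks with more than 10 frames); the
    dropped count is logged.
    """
    mapping = mapping or ColumnMapping()
    df = _read_table(path, [mapping.frame, mapping.x, mapping.y])
    if mapping.track_id not in df.columns:
        raise ValueError(f"missing required column(s) ['{mapping.track_id}']")
    scale = _UNIT_TO_UM[mapping.unit]
    trajs = []
    dropped = 0
    for tid, grp in df.groupby(mapping.track_id, sort=True):
        grp = grp.sort_values(mapping.frame)
        if len(grp) < min_frames:
            dropped += 1
            continue
        trajs.append(
            Trajectory(
                track_id=tid,
                frames=grp[mapping.frame].to_numpy(dtype=np.int64),
                positions=scale
                * grp[[mapping.x, mapping.y]].to_numpy(dtype=float),
                frame_interval=mapping.frame_interval,
            )
        )
    if dropped:
        logger.info(
            "dropped %d track(s) shorter than %d frames", dropped, min_frames
        )
    return trajs


def write_tracks(trajs: list[Trajectory], path: str | Path) -> None:
    """Write trajectories as a (track_id, frame, x_um, y_um) CSV."""
    rows = []
    for t in trajs:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.9f")


def read_localizations(
    path: str | Path, unit: str = "nm"
) -> pd.DataFrame:
    """Read a localization table (frame, x, y[, precision]) into nm.

    Accepts columns named (frame, x_nm, y_nm) or (frame, x, y); rows
    with negative or non-finite coordinates are rejected with a logged
    count.
    """
    if unit not in _UNIT_TO_NM:
        raise ValueError("unit must be 'um' or 'nm'")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{Path(path).name}: empty localization file")
    cols = {c.lower(): c for c in df.columns}
    names = {}
    for want, options in {
        "frame": ("frame",),
        "x_nm": ("x_nm", "x", "x_um"),
        "y_nm": ("y_nm", "y", "y_um"),
    }.items():
        for opt in options:
            if opt in cols:
                names[want] = cols[opt]
                break
        else:
            raise ValueError(f"{Path(path).name}: missing column for '{want}'")
    scale = _UNIT_TO_NM[unit]
    out = pd.DataFrame(
        {
            "frame": pd.to_numeric(df[names["frame"]]).astype(np.int64),
            "x_nm": scale * pd.to_numeric(df[names["x_nm"]]),
            "y_nm": scale * pd.to_numeric(df[names["y_nm"]]),
        }
    )
    ok = (
        np.isfinite(out["x_nm"])
        & np.isfinite(out["y_nm"])
        & (out["x_nm"] >= 0)
        & (out["y_nm"] >= 0)
        & (out["frame"] >= 0)
    )
    if (~ok).any():
        logger.info("rejected %d invalid localization row(s)", int((~ok).sum()))
    return out.loc[ok].reset_index(drop=True)


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def write_trace_csv(trace, path: str | Path) -> None:
    """Simulation trace as (step, mean_radius, condensed_fraction) CSV."""
    pd.DataFrame(
        {
            "step": trace.times,
            "mean_radius": trace.mean_radius,
            "condensed_fraction": trace.condensed_fraction,
        }
    ).to_csv(path, index=False)


def write_report(
    results: dict, path: str | Path, config: dict | None = None
) -> None:
    """JSON summary embedding the run configuration and package version.

    Keys are written in sorted order so identical runs produce identical
    files apart from the timestamp field.
    """
    from . import __version__

    payload = {
        "condyn_version": __version__,
        "config": _jsonable(config or {}),
        "results": _jsonable(results),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj
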