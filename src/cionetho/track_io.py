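"""Reading tracking tables and calibrating them to arena-centred millimetres.

Centroid trackers export per-frame pixel positions of each detected animal.
This module parses two table dialects (a ToxTrac-style whitespace-delimited
export and a generic CSV), converts pixel coordinates into millimetres with
the origin at the arena centre, and applies the trace-exclusion rules used
throughout the analysis (too-short traces and immobile animals that are
indistinguishable from dead ones).

Conventions
-----------
* Pixel input uses the image convention (y grows downward); calibrated
  millimetre coordinates use the mathematical convention (y grows upward),
  so the y axis is flipped during calibration.
* Frames that fall between the first and last observation of a track but
  are absent from the table are kept as masked gaps — they are never
  interpolated; downstream windowed computations treat them as invalid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("cionetho")

__all__ = [
    "TrackTable",
    "ArenaGeometry",
    "Trajectory",
    "QCReport",
    "read_toxtrac",
    "read_csv_tracks",
    "calibrate",
    "uncalibrate",
    "qc_filter",
]

#: Columns of the generic CSV dialect, in order.
CSV_COLUMNS = ("frame", "track_id", "x_px", "y_px")

#: Columns of the ToxTrac-style whitespace-delimited dialect, in order.
TOXTRAC_COLUMNS = ("frame", "arena", "track", "x", "y")


@dataclass
class TrackTable:
    """Raw tracker output: one row per (frame, track) observation.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``frame`` (int), ``track_id`` (int), ``x_px``, ``y_px``
        (float, pixels). Within each ``track_id`` frames are strictly
        increasing.
    fps : float
        Recording frame rate in Hz.
    source : str
        Where the table came from (file path or generator tag).
    n_malformed : int
        Number of input rows that could not be parsed and were skipped.
    """

    data: pd.DataFrame
    fps: float
    source: str = ""
    n_malformed: int = 0

    def __post_init__(self) -> None:
        if (self.data["frame"] < 0).any():
            raise ValueError("frame indices must be non-negative")
        for tid, sub in self.data.groupby("track_id"):
            if not np.all(np.diff(sub["frame"].to_numpy()) > 0):
                raise ValueError(f"frames not strictly increasing in track {tid}")

    @property
    def track_ids(self) -> list[int]:
        return sorted(self.data["track_id"].unique().tolist())


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular arena position and size in the image, plus physical size.

    The default physical dimensions correspond to a 10 mm diameter, 3 mm
    deep well (volume ~236 mm^3).
    """

    centre_px: tuple[float, float]
    radius_px: float
    radius_mm: float = 5.0
    height_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    @property
    def scale(self) -> float:
        """Calibration factor in mm per pixel."""
        s = self.radius_mm / self.radius_px
        if not np.isfinite(s) or s <= 0:
            raise ValueError("arena scale must be finite and positive")
        return s

    @property
    def volume_mm3(self) -> float:
        """Arena volume pi * r^2 * h in mm^3."""
        return float(np.pi * self.radius_mm**2 * self.height_mm)


@dataclass
class Trajectory:
    """Calibrated per-animal time series in arena-centred millimetres.

    ``gap_mask`` is True where the frame is missing (tracker dropout);
    positions at masked frames are NaN and must not be used.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    gap_mask: np.ndarray
    animal_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.gap_mask) == n):
            raise ValueError("t, x, y and gap_mask must have equal length")
        if n > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fps, rtol=0, atol=1e-9 / self.fps):
                raise ValueError("time axis must be uniform with step 1/fps")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int((~self.gap_mask).sum())

    @property
    def r(self) -> np.ndarray:
        """Distance from the arena centre, mm."""
        return np.hypot(self.x, self.y)


@dataclass(frozen=True)
class QCReport:
    """Outcome of the trace-exclusion filter for one animal."""

    animal_id: str
    kept: bool
    reason: str  # "ok" | "immobile" | "too_short"
    max_displacement: float
    n_frames: int

    def __post_init__(self) -> None:
        if (self.reason == "ok") != self.kept:
            raise ValueError("reason must be 'ok' iff kept")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _finalize_rows(rows: pd.DataFrame, n_bad: int, fps: float, source: str) -> TrackTable:
    if len(rows) == 0:
        raise ValueError(f"no parseable rows in {source!r}")
    if n_bad:
        msg = f"{source}: skipped {n_bad} malformed row(s)"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=3)
    rows = rows.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return TrackTable(data=rows, fps=fps, source=source, n_malformed=n_bad)


def read_toxtrac(path, fps: float) -> TrackTable:
    """Read a ToxTrac-style whitespace-delimited track export.

    Expected columns (a header line is tolerated and skipped):
    ``frame arena track x y``. Malformed rows are skipped with a logged
    count rather than aborting the whole file.
    """
    raw = pd.read_csv(
        path, sep=r"\s+", header=None, names=TOXTRAC_COLUMNS, comment="#",
        dtype=str, skip_blank_lines=True,
    )
    if len(raw) == 0:
        raise ValueError(f"empty file: {path!r}")
    frame = pd.to_numeric(raw["frame"], errors="coerce")
    track = pd.to_numeric(raw["track"], errors="coerce")
    x = pd.to_numeric(raw["x"], errors="coerce")
    y = pd.to_numeric(raw["y"], errors="coerce")
    ok = frame.notna() & track.notna() & x.notna() & y.notna()
    rows = pd.DataFrame(
        {
            "frame": frame[ok].astype(int),
            "track_id": track[ok].astype(int),
            "x_px": x[ok].astype(float),
            "y_px": y[ok].astype(float),
        }
    )
    # a header line parses as all-NaN and is not counted as malformed
    n_bad = int((~ok).sum())
    if n_bad and not ok.iloc[0]:
        n_bad -= 1
    return _finalize_rows(rows, n_bad, fps, str(path))


def read_csv_tracks(path, fps: float, schema: dict[str, str] | None = None) -> TrackTable:
    """Read the generic CSV dialect ``frame,track_id,x_px,y_px``.

    Parameters
    ----------
    schema
        Optional mapping from required column names to the names actually
        present in the file header, e.g. ``{"x_px": "X"}``.
    """
    raw = pd.read_csv(path, dtype=str, comment="#")
    if len(raw) == 0:
        raise ValueError(f"empty file: {path!r}")
    schema = schema or {}
    colmap = {req: schema.get(req, req) for req in CSV_COLUMNS}
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path!r}")
    cols = {req: pd.to_numeric(raw[src], errors="coerce") for req, src in colmap.items()}
    ok = np.logical_and.reduce([c.notna().to_numpy() for c in cols.values()])
    rows = pd.DataFrame(
        {
            "frame": cols["frame"][ok].astype(int),
            "track_id": cols["track_id"][ok].astype(int),
            "x_px": cols["x_px"][ok].astype(float),
            "y_px": cols["y_px"][ok].astype(float),
        }
    )
    return _finalize_rows(rows, int((~ok).sum()), fps, str(path))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(table: TrackTable, arena: ArenaGeometry) -> list[Trajectory]:
    """Convert a pixel track table into arena-centred millimetre trajectories.

    One :class:`Trajectory` per ``track_id``. The affine map is
    ``x_mm = (x_px - cx) * s`` and ``y_mm = -(y_px - cy) * s`` with
    ``s = radius_mm / radius_px`` (the y flip converts from image to
    mathematical axis convention). Frames absent between the first and last
    observation of a track become masked gaps.
    """
    s = arena.scale
    cx, cy = arena.centre_px
    out: list[Trajectory] = []
    for tid, sub in table.data.groupby("track_id"):
        frames = sub["frame"].to_numpy()
        f0, f1 = int(frames[0]), int(frames[-1])
        n = f1 - f0 + 1
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        gap = np.ones(n, dtype=bool)
        idx = frames - f0
        x[idx] = (sub["x_px"].to_numpy() - cx) * s
        y[idx] = -(sub["y_px"].to_numpy() - cy) * s
        gap[idx] = False
        t = (f0 + np.arange(n)) / table.fps
        out.append(
            Trajectory(t=t, x=x, y=y, fps=table.fps, gap_mask=gap, animal_id=str(tid))
        )
    return out


def uncalibrate(traj: Trajectory, arena: ArenaGeometry, track_id: int = 0) -> pd.DataFrame:
    """Inverse of :func:`calibrate`: mm trajectory back to a pixel row table."""
    s = arena.scale
    cx, cy = arena.centre_px
    valid = ~traj.gap_mask
    frames = np.round(traj.t * traj.fps).astype(int)
    return pd.DataFrame(
        {
            "frame": frames[valid],
            "track_id": track_id,
            "x_px": traj.x[valid] / s + cx,
            "y_px": -traj.y[valid] / s + cy,
        }
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(
    traj: Trajectory, min_frames: int = 2000, body_length_mm: float = 1.0
) -> QCReport:
    """Apply the trace-exclusion rules.

    A trace is excluded as ``immobile`` when its maximal displacement from
    the starting position stays below one body length (such animals are
    indistinguishable from dead), and as ``too_short`` when it holds fewer
    than ``min_frames`` observed frames. Immobility takes precedence; when
    both apply, both are logged.
    """
    valid = ~traj.gap_mask
    n_obs = int(valid.sum())
    if n_obs == 0:
        return QCReport(traj.animal_id, False, "too_short", 0.0, 0)
    xs, ys = traj.x[valid], traj.y[valid]
    disp = np.hypot(xs - xs[0], ys - ys[0])
    max_disp = float(disp.max())
    immobile = max_disp < body_length_mm
    too_short = n_obs < min_frames
    if immobile and too_short:
        logger.info("%s excluded: immobile and too_short", traj.animal_id)
    if immobile:
        return QCReport(traj.animal_id, False, "immobile", max_disp, n_obs)
    if too_short:
        return QCReport(traj.animal_id, False, "too_short", max_disp, n_obs)
    return QCReport(traj.animal_id, True, "ok", max_disp, n_obs)
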