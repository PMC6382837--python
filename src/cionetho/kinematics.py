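"""Kinematic descriptors of calibrated larval trajectories.

Two speed notions coexist, both in um/s:

* the **filtered speed** — frame-to-frame displacement speed passed through
  a zero-phase 1 Hz low-pass filter, used for the activity coefficient and
  the per-animal speed summaries (it removes the high-frequency jitter of
  the undulating head during swimming);
* the **lag speed** ``rho`` — displacement measured between coordinates 5
  frames apart, which together with the heading ``theta``, turn
  ``dtheta = wrap(theta_{t+lag} - theta_t)`` and acceleration
  ``drho = rho_{t+lag} - rho_t`` feeds the behavioural-mode features. The
  5-frame lag serves the same purpose as the filter for angular measures.

Frames adjacent to tracker gaps, and filter warm-up frames at segment
edges, are marked invalid rather than interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .track_io import Trajectory

__all__ = [
    "KinematicSeries",
    "BehaviouralSummary",
    "AcclimatizationProfile",
    "wrap_angle",
    "filtered_speed",
    "lag_kinematics",
    "activity_coefficient",
    "summarize",
    "acclimatization_profile",
]

#: default low-pass cutoff for speed filtering, Hz
FILTER_CUTOFF_HZ = 1.0
#: default displacement lag for velocity vectors, frames
LAG_FRAMES = 5
#: default activity threshold on filtered speed, um/s
ACTIVITY_THRESHOLD_UM_S = 200.0


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    w = (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


@dataclass
class KinematicSeries:
    """Per-frame kinematics of one animal (NaN marks invalid entries)."""

    speed: np.ndarray  # 1 Hz low-pass filtered frame-to-frame speed, um/s
    rho: np.ndarray    # lag-displacement speed, um/s
    theta: np.ndarray  # heading of the lag-displacement vector, rad
    turn: np.ndarray   # wrapped heading change over one lag, rad, (-pi, pi]
    accel: np.ndarray  # rho change over one lag, um/s per lag step
    lag: int
    fps: float
    valid_mask: np.ndarray  # rows where rho, turn and accel are all defined

    def __post_init__(self) -> None:
        n = len(self.rho)
        if not all(
            len(a) == n
            for a in (self.speed, self.theta, self.turn, self.accel, self.valid_mask)
        ):
            raise ValueError("all series must have equal length")


@dataclass(frozen=True)
class BehaviouralSummary:
    """Scalar behavioural descriptors of one animal."""

    animal_id: str
    median_speed: float  # um/s, filtered
    max_speed: float     # um/s, filtered
    AC: float            # activity coefficient, fraction of active time
    min_complexity: float  # bits
    TTO: float           # fraction of time in the outer zone
    TDO: float           # fraction of distance in the outer zone
    median_dist_centre: float  # mm

    def __post_init__(self) -> None:
        for name in ("AC", "TTO", "TDO"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.max_speed >= self.median_speed >= 0:
            raise ValueError("need max_speed >= median_speed >= 0")


@dataclass
class AcclimatizationProfile:
    """Cohort-average speed stabilisation after introduction to the arena."""

    time: np.ndarray              # s
    mean_speed_curve: np.ndarray  # um/s, cohort average
    window_starts: np.ndarray     # s
    slopes: np.ndarray            # um/s per s, OLS within each window
    stabilization_time: float | None


# ---------------------------------------------------------------------------
# Speed
# ---------------------------------------------------------------------------

def frame_speed(traj: Trajectory) -> np.ndarray:
    """Unfiltered frame-to-frame displacement speed, um/s (NaN at gaps/end)."""
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    v = np.hypot(dx, dy) * traj.fps * 1e3  # mm/frame -> um/s
    return np.append(v, np.nan)


def filtered_speed(traj: Trajectory, cutoff: float = FILTER_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase low-pass-filtered frame-to-frame speed series, um/s.

    The per-frame velocity *components* are filtered with a 4th-order
    Butterworth applied forward-backward (``sosfiltfilt``) over each
    contiguous gap-free segment, and the speed is the magnitude of the
    filtered velocity. Filtering the components rather than the rectified
    speed magnitude matters: a perpendicular head-undulation tone above
    the cutoff inflates the *mean* of the raw speed (rectification folds
    it into DC), so only component-wise filtering recovers the underlying
    drift speed. Filter warm-up frames at segment edges, segments too
    short to filter, and frames touching gaps come out NaN.
    """
    if traj.fps <= 2 * cutoff:
        raise ValueError("fps must exceed twice the filter cutoff")
    vx = np.append(np.diff(traj.x), np.nan) * traj.fps * 1e3  # um/s
    vy = np.append(np.diff(traj.y), np.nan) * traj.fps * 1e3
    out = np.full_like(vx, np.nan)
    sos = butter(4, cutoff, btype="low", fs=traj.fps, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    edge = int(round(traj.fps / cutoff))  # warm-up margin, ~1 filter period
    valid = np.isfinite(vx) & np.isfinite(vy)
    # contiguous runs of valid samples
    idx = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    for s, e in idx.reshape(-1, 2):
        if e - s <= padlen:
            continue
        fx = sosfiltfilt(sos, vx[s:e])
        fy = sosfiltfilt(sos, vy[s:e])
        lo, hi = s + min(edge, (e - s) // 2), e - min(edge, (e - s) // 2)
        out[lo:hi] = np.hypot(fx, fy)[lo - s : hi - s]
    return out


# ---------------------------------------------------------------------------
# Lag kinematics
# ---------------------------------------------------------------------------

def lag_kinematics(traj: Trajectory, lag: int = LAG_FRAMES,
                   cutoff: float = FILTER_CUTOFF_HZ) -> KinematicSeries:
    """Velocity vectors from coordinates ``lag`` frames apart.

    ``rho[t]`` and ``theta[t]`` describe the displacement from frame ``t``
    to ``t + lag``; ``turn[t]`` and ``accel[t]`` compare the vectors at
    ``t`` and ``t + lag``. Entries touching masked frames are NaN.
    """
    n = traj.n_frames
    if n <= 2 * lag:
        raise ValueError("trajectory must be longer than twice the lag")
    x, y = traj.x, traj.y
    rho = np.full(n, np.nan)
    theta = np.full(n, np.nan)
    dx = x[lag:] - x[:-lag]
    dy = y[lag:] - y[:-lag]
    rho[: n - lag] = np.hypot(dx, dy) * traj.fps / lag * 1e3  # um/s
    theta[: n - lag] = np.arctan2(dy, dx)
    turn = np.full(n, np.nan)
    accel = np.full(n, np.nan)
    turn[: n - 2 * lag] = wrap_angle(theta[lag : n - lag] - theta[: n - 2 * lag])
    accel[: n - 2 * lag] = rho[lag : n - lag] - rho[: n - 2 * lag]
    # zero-length lag displacements have undefined heading; keep theta from
    # atan2 (0) but that is arbitrary — mark turns meaningless only via NaN
    # positions, which propagate automatically.
    valid = np.isfinite(rho) & np.isfinite(turn) & np.isfinite(accel)
    return KinematicSeries(
        speed=filtered_speed(traj, cutoff=cutoff),
        rho=rho, theta=theta, turn=turn, accel=accel,
        lag=lag, fps=traj.fps, valid_mask=valid,
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def activity_coefficient(
    speed: np.ndarray, threshold: float = ACTIVITY_THRESHOLD_UM_S
) -> float:
    """Fraction of valid frames whose filtered speed is >= ``threshold``."""
    v = np.asarray(speed, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("no valid frames for activity coefficient")
    return float((v[ok] >= threshold).sum() / ok.sum())


def summarize(traj: Trajectory, kin: KinematicSeries, complexity_series, thigmo,
              threshold: float = ACTIVITY_THRESHOLD_UM_S) -> BehaviouralSummary:
    """Collapse one animal's series into a :class:`BehaviouralSummary`.

    ``complexity_series`` is a :class:`~cionetho.complexity.ComplexitySeries`
    and ``thigmo`` a :class:`~cionetho.thigmotaxis.ThigmoMetrics`.
    """
    ok = np.isfinite(kin.speed)
    if not ok.any():
        raise ValueError("no valid filtered-speed frames to summarise")
    sp = kin.speed[ok]
    from .complexity import min_complexity  # local to avoid cycle

    return BehaviouralSummary(
        animal_id=traj.animal_id,
        median_speed=float(np.median(sp)),
        max_speed=float(sp.max()),
        AC=activity_coefficient(kin.speed, threshold=threshold),
        min_complexity=min_complexity(complexity_series),
        TTO=thigmo.TTO,
        TDO=thigmo.TDO,
        median_dist_centre=thigmo.median_dist,
    )


def acclimatization_profile(
    trajs: list[Trajectory],
    window: float = 300.0,
    step: float = 10.0,
    slope_tol: float = 0.05,
    cutoff: float = FILTER_CUTOFF_HZ,
) -> AcclimatizationProfile:
    """Cohort speed-stabilisation profile (sliding-window regression slopes).

    The cohort-average filtered speed is regressed against time inside
    sliding windows (default 5 min, stepped by 10 s); stabilisation is the
    start of the first window whose absolute slope drops below
    ``slope_tol`` (um/s per s) and stays below for every later window.
    """
    if not trajs:
        raise ValueError("empty cohort")
    fps = trajs[0].fps
    n = max(t.n_frames for t in trajs)
    if n < window * fps:
        raise ValueError("recording shorter than one window")
    stack = np.full((len(trajs), n), np.nan)
    for i, tr in enumerate(trajs):
        stack[i, : tr.n_frames] = filtered_speed(tr, cutoff=cutoff)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_curve = np.nanmean(stack, axis=0)
    tsec = np.arange(n) / fps
    wlen = int(round(window * fps))
    stp = max(1, int(round(step * fps)))
    starts, slopes = [], []
    for s in range(0, n - wlen + 1, stp):
        seg = mean_curve[s : s + wlen]
        tt = tsec[s : s + wlen]
        ok = np.isfinite(seg)
        if ok.sum() < 2:
            starts.append(tsec[s])
            slopes.append(np.nan)
            continue
        slope = np.polyfit(tt[ok], seg[ok], 1)[0]
        starts.append(tsec[s])
        slopes.append(float(slope))
    slopes_a = np.array(slopes)
    starts_a = np.array(starts)
    below = np.abs(slopes_a) < slope_tol
    stab: float | None = None
    for i in range(len(below)):
        if below[i:].all():
            stab = float(starts_a[i])
            break
    return AcclimatizationProfile(
        time=tsec,
        mean_speed_curve=mean_curve,
        window_starts=starts_a,
        slopes=slopes_a,
        stabilization_time=stab,
    )
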