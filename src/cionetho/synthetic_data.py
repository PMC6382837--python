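"""Seeded generator of ground-truth-labelled larval swimming trajectories.

Free-swimming ascidian larvae alternate between bouts of inactivity,
sub-body-length twitching and swimming bursts that reach roughly
1,500-1,900 um/s, inside a 10 mm circular arena whose wall they may follow
(thigmotaxis). The generator emulates that structure with a regime-switching
(Markov) random walk:

* a finite set of :class:`ModeRegime` locomotor regimes, each with a mean
  speed, speed variability, heading persistence and mean dwell time;
* geometric dwell times via the self-transition probability
  ``p_stay = 1 - 1/(fps * mean_dwell)``;
* per-frame displacement magnitudes drawn from a gamma distribution around
  ``mean_speed / fps`` with the regime's coefficient of variation, and
  heading increments drawn from a wrapped-normal-like distribution with
  standard deviation ``1/sqrt(turn_concentration)``;
* twitch regimes produce zero-mean jitter anchored to the entry position
  (centre-point motion from tail flicks, without net displacement);
* a perpendicular head-undulation sinusoid superimposed during active
  swimming (tail beating), by default 5 Hz / 50 um — above the 1 Hz
  speed-filter cutoff and below one body length;
* wall contact projects the position back inside the arena and, with
  probability ``wall_bias``, aligns the heading with the wall tangent
  (wall following); otherwise the heading is specularly reflected;
* a fraction ``dropout_rate`` of frames is marked missing, emulating
  tracker dropout.

Everything is driven by a single master seed; per-animal seeds are derived
by fixed increments so cohorts are reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .track_io import ArenaGeometry, TrackTable, Trajectory, uncalibrate

__all__ = [
    "ModeRegime",
    "SimConfig",
    "LabelledTrajectory",
    "default_mode_library",
    "default_transition_matrix",
    "generate_trajectory",
    "generate_cohort",
    "write_csv_tracks",
    "write_toxtrac",
    "write_truth_modes",
]

#: activity threshold (um/s) above which a regime is considered to involve
#: tail beating, hence head undulation
ACTIVE_SPEED_UM_S = 200.0

#: radius (mm) of the leash that keeps twitch jitter sub-body-length
TWITCH_ANCHOR_MM = 0.5


@dataclass(frozen=True)
class ModeRegime:
    """One locomotor regime of the switching random walk.

    Parameters
    ----------
    name : str
        Human-readable label.
    mean_speed : float
        Mean unfiltered speed, um/s.
    speed_cv : float
        Coefficient of variation of per-frame displacement magnitudes.
    turn_concentration : float
        Concentration of heading increments (wrapped-normal kappa-like;
        higher means straighter paths). Ignored for twitch regimes, whose
        heading is redrawn uniformly every frame.
    mean_dwell : float
        Mean time spent in the regime per visit, s.
    is_twitch : bool
        Sub-body-length oscillatory displacement anchored in place.
    """

    name: str
    mean_speed: float
    speed_cv: float
    turn_concentration: float
    mean_dwell: float
    is_twitch: bool = False

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.speed_cv <= 0:
            raise ValueError("speed_cv must be > 0")
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be > 0")


def default_mode_library() -> list[ModeRegime]:
    """The default 11-regime library mirroring the larval mode ontology.

    Regimes are ordered by approximate speed of movement, from quiescence
    through twitching to fast swimming bursts: inactive regimes sit below
    the 200 um/s activity threshold, swimming regimes reach ~1,900 um/s
    with increasingly straight paths, and long inactive dwell times make
    quiescence dominate occupancy as in spontaneous recordings. Twitch
    regimes displace the centroid vigorously per frame but with randomised
    direction, so their *observed* lag-5 speed is roughly 0.4x the nominal
    per-step speed.

    Because the mode ontology is meant to be recoverable by windowed-feature
    clustering, the library is calibrated to be kinematically well
    separated under that analysis: every dwell time comfortably exceeds
    the 1.7 s feature window (episodes shorter than the window cannot
    produce a pure observation), adjacent regimes are separated in
    observed lag-speed by at least ~3x their feature spread, and the
    speed spacing balances occupancy so no pair of regimes is
    overwhelmingly cheaper to confuse than any other.
    """
    return [
        ModeRegime("Inactive 1", 15.0, 0.6, 0.5, 30.0),
        ModeRegime("Inactive 2", 141.0, 0.5, 5.0, 18.0),
        ModeRegime("Small twitches", 698.0, 0.3, 0.5, 7.5, is_twitch=True),
        ModeRegime("Large twitches", 1170.0, 0.25, 0.5, 6.0, is_twitch=True),
        ModeRegime("Collision/Deceleration", 755.0, 0.25, 2.0, 5.25),
        ModeRegime("Mode change 1", 904.0, 0.22, 4.0, 5.25),
        ModeRegime("Mode change 2", 1120.0, 0.22, 6.0, 5.25),
        ModeRegime("Slow active swimming", 1303.0, 0.2, 10.0, 7.5),
        ModeRegime("Medium active swimming", 1460.0, 0.18, 15.0, 7.5),
        ModeRegime("Fast swimming 1", 1635.0, 0.15, 25.0, 6.0),
        ModeRegime("Fast swimming 2", 1885.0, 0.12, 40.0, 5.25),
    ]


def default_transition_matrix(
    regimes: list[ModeRegime], fps: float, adjacency_scale: float = 2.0
) -> np.ndarray:
    """Row-stochastic transition matrix with geometric dwell times.

    Self-transition probability ``p_stay = 1 - 1/(fps * mean_dwell)``
    clamped to [0, 1). The remaining mass favours kinematically adjacent
    regimes (weights ``exp(-|i - j| / adjacency_scale)`` over the
    speed-ordered library): locomotor state changes pass through
    neighbouring intensities rather than jumping arbitrarily.
    """
    k = len(regimes)
    if k == 1:
        return np.ones((1, 1))
    T = np.empty((k, k))
    idx = np.arange(k)
    for i, reg in enumerate(regimes):
        p_stay = float(np.clip(1.0 - 1.0 / (fps * reg.mean_dwell), 0.0, 1.0 - 1e-9))
        w = np.exp(-np.abs(idx - i) / adjacency_scale)
        w[i] = 0.0
        T[i] = (1.0 - p_stay) * w / w.sum()
        T[i, i] = p_stay
    return T


@dataclass
class SimConfig:
    """Full description of one simulated recording.

    Defaults emulate the study's baseline recordings: 5 min at 30 fps in a
    10 mm diameter arena, with 5 Hz / 50 um head undulation.
    """

    regimes: list[ModeRegime] = field(default_factory=default_mode_library)
    transition_matrix: np.ndarray | None = None
    fps: float = 30.0
    duration: float = 300.0
    arena_radius: float = 5.0
    wall_bias: float = 0.3
    undulation_amp: float = 50.0
    undulation_freq: float = 5.0
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.regimes, self.fps)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.regimes)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition_matrix shape must match number of regimes")
        rowsums = self.transition_matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, rtol=0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1 +- 1e-9")
        if not 0.0 <= self.wall_bias <= 1.0:
            raise ValueError("wall_bias must be in [0, 1]")
        if self.undulation_freq <= 1.0:
            raise ValueError("undulation_freq must exceed 1 Hz")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regimes"] = [dataclasses.asdict(r) for r in self.regimes]
        d["transition_matrix"] = np.asarray(self.transition_matrix).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["regimes"] = [ModeRegime(**r) for r in d["regimes"]]
        if d.get("transition_matrix") is not None:
            d["transition_matrix"] = np.asarray(d["transition_matrix"], dtype=float)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LabelledTrajectory:
    """A simulated trajectory with its per-frame ground-truth regime index."""

    trajectory: Trajectory
    true_modes: np.ndarray
    config: SimConfig

    def __post_init__(self) -> None:
        if len(self.true_modes) != self.trajectory.n_frames:
            raise ValueError("true_modes must have one entry per frame")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, i]))
    return pi / pi.sum()


def _sample_regime_path(T: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    k = T.shape[0]
    cum = np.cumsum(T, axis=1)
    u = rng.random(n)
    path = np.empty(n, dtype=np.intp)
    path[0] = rng.choice(k, p=_stationary_distribution(T))
    for t in range(1, n):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def generate_trajectory(config: SimConfig) -> LabelledTrajectory:
    """Simulate one animal according to ``config``.

    Deterministic given ``config.seed``. See the module docstring for the
    generative model; positions are returned in arena-centred mm.
    """
    n = config.n_frames
    if n < 2:
        raise ValueError("duration * fps must give at least 2 frames")
    rng = np.random.default_rng(config.seed)
    regimes = config.regimes
    path = _sample_regime_path(config.transition_matrix, n, rng)

    # per-frame step magnitudes (mm) and heading increments, drawn per regime
    step = np.zeros(n)
    dtheta = np.zeros(n)
    uniform_heading = np.zeros(n, dtype=bool)
    for i, reg in enumerate(regimes):
        sel = path == i
        m = int(sel.sum())
        if m == 0:
            continue
        mean_step = reg.mean_speed / config.fps * 1e-3  # um/s -> mm/frame
        if mean_step > 0:
            shape = 1.0 / reg.speed_cv**2
            step[sel] = rng.gamma(shape, mean_step / shape, size=m)
        if reg.is_twitch:
            uniform_heading[sel] = True
        else:
            sigma = 1.0 / np.sqrt(max(reg.turn_concentration, 1e-12))
            dtheta[sel] = rng.normal(0.0, sigma, size=m)
    uheads = rng.uniform(-np.pi, np.pi, size=n)

    R = config.arena_radius
    x = np.empty(n)
    y = np.empty(n)
    # start at a uniform position in the inner half of the disc
    r0 = R * 0.7 * np.sqrt(rng.random())
    a0 = rng.uniform(-np.pi, np.pi)
    x[0], y[0] = r0 * np.cos(a0), r0 * np.sin(a0)
    heading = rng.uniform(-np.pi, np.pi)
    wall_u = rng.random(n)
    anchor_x, anchor_y = x[0], y[0]
    prev_regime = path[0]

    for t in range(1, n):
        reg_i = path[t]
        if regimes[reg_i].is_twitch:
            if reg_i != prev_regime:
                anchor_x, anchor_y = x[t - 1], y[t - 1]
            dx_a = anchor_x - x[t - 1]
            dy_a = anchor_y - y[t - 1]
            if dx_a * dx_a + dy_a * dy_a > TWITCH_ANCHOR_MM**2:
                heading = np.arctan2(dy_a, dx_a)  # pull back toward anchor
            else:
                heading = uheads[t]
        else:
            heading = heading + dtheta[t]
        px = x[t - 1] + step[t] * np.cos(heading)
        py = y[t - 1] + step[t] * np.sin(heading)
        rr = np.hypot(px, py)
        if rr > R:
            px *= R / rr * (1.0 - 1e-9)
            py *= R / rr * (1.0 - 1e-9)
            nx, ny = px / R, py / R  # outward normal
            if wall_u[t] < config.wall_bias:
                # align with the wall tangent, keeping the direction of travel
                tx, ty = -ny, nx
                if tx * np.cos(heading) + ty * np.sin(heading) < 0:
                    tx, ty = -tx, -ty
                heading = np.arctan2(ty, tx)
            else:
                # specular reflection off the wall
                hx, hy = np.cos(heading), np.sin(heading)
                dot = hx * nx + hy * ny
                heading = np.arctan2(hy - 2 * dot * ny, hx - 2 * dot * nx)
        x[t], y[t] = px, py
        prev_regime = reg_i

    # head undulation during active (tail-beating) swimming
    if config.undulation_amp > 0:
        active = np.array(
            [(not r.is_twitch) and r.mean_speed >= ACTIVE_SPEED_UM_S for r in regimes]
        )[path]
        if active.any():
            tsec = np.arange(n) / config.fps
            # heading of travel from finite differences (for the normal)
            hx = np.gradient(x)
            hy = np.gradient(y)
            norm = np.hypot(hx, hy)
            norm[norm == 0] = 1.0
            amp = config.undulation_amp * 1e-3  # um -> mm
            osc = amp * np.sin(2 * np.pi * config.undulation_freq * tsec)
            x = x + np.where(active, -hy / norm * osc, 0.0)
            y = y + np.where(active, hx / norm * osc, 0.0)
            rr = np.hypot(x, y)
            out = rr > R
            if out.any():
                f = R / rr[out] * (1.0 - 1e-9)
                x[out] *= f
                y[out] *= f

    # bursty tracker dropout: missing frames arrive in runs (occlusion
    # episodes, mean ~0.5 s), matching the banded structure of real gaps
    gap = np.zeros(n, dtype=bool)
    if config.dropout_rate > 0:
        n_drop = int(round(config.dropout_rate * n))
        mean_run = max(1, int(round(0.5 * config.fps)))
        dropped = 0
        while dropped < n_drop:
            start = int(rng.integers(0, n))
            run = 1 + int(rng.geometric(1.0 / mean_run))
            run = min(run, n_drop - dropped, n - start)
            if run <= 0:
                continue
            gap[start : start + run] = True
            dropped = int(gap.sum())
        x = x.copy()
        y = y.copy()
        x[gap] = np.nan
        y[gap] = np.nan

    traj = Trajectory(
        t=np.arange(n) / config.fps,
        x=x,
        y=y,
        fps=config.fps,
        gap_mask=gap,
        animal_id=f"sim-{config.seed}",
    )
    return LabelledTrajectory(trajectory=traj, true_modes=path, config=config)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: SimConfig scalar fields that a cohort override may set directly
_OVERRIDE_FIELDS = {
    "fps",
    "duration",
    "arena_radius",
    "wall_bias",
    "undulation_amp",
    "undulation_freq",
    "dropout_rate",
}


def _apply_overrides(config: SimConfig, overrides: dict) -> SimConfig:
    d = config.to_dict()
    explicit_T = config.transition_matrix.copy()
    fps_changed = False
    for key, value in overrides.items():
        if key in _OVERRIDE_FIELDS:
            d[key] = value
            fps_changed = fps_changed or key == "fps"
        elif key == "speed_scale":
            d["regimes"] = [
                {**r, "mean_speed": r["mean_speed"] * value} for r in d["regimes"]
            ]
        elif key == "occupancy_boost":
            T = explicit_T.copy()
            names = [r["name"] for r in d["regimes"]]
            for name, factor in value.items():
                if name not in names:
                    raise KeyError(f"unknown regime name in occupancy_boost: {name!r}")
                T[:, names.index(name)] *= factor
            T /= T.sum(axis=1, keepdims=True)
            explicit_T = T
        else:
            raise KeyError(f"unknown override key: {key!r}")
    if fps_changed and "occupancy_boost" not in overrides:
        d["transition_matrix"] = None  # rebuild dwell-consistent matrix
    else:
        d["transition_matrix"] = explicit_T
    cfg = SimConfig.from_dict(d)
    return cfg


def generate_cohort(
    n: int,
    config: SimConfig,
    overrides: dict | None = None,
    id_prefix: str | None = None,
) -> list[LabelledTrajectory]:
    """Simulate ``n`` animals with seeds ``config.seed + i``.

    ``overrides`` may set any of the scalar config fields
    (``wall_bias``, ``dropout_rate``, ...), scale all regime speeds
    (``speed_scale``) or re-weight regime occupancy
    (``occupancy_boost={regime_name: factor}``), e.g. to emulate a
    stimulant-exposed group with more fast swimming and stronger wall
    following. Unknown keys raise ``KeyError``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    cfg = _apply_overrides(config, overrides) if overrides else config
    prefix = id_prefix if id_prefix is not None else f"sim-{cfg.seed}"
    out = []
    for i in range(n):
        ci = dataclasses.replace(cfg, seed=int((cfg.seed + i) % 2**31))
        # replace() reuses the validated matrix; keep it explicit
        ci.transition_matrix = cfg.transition_matrix
        lab = generate_trajectory(ci)
        lab.trajectory.animal_id = f"{prefix}-{i:03d}"
        out.append(lab)
    return out


# ---------------------------------------------------------------------------
# Writers (round-trip with track_io readers)
# ---------------------------------------------------------------------------

def _default_arena(config: SimConfig) -> ArenaGeometry:
    # 0.02 mm/px: a 5 mm radius arena imaged at 250 px radius
    return ArenaGeometry(centre_px=(256.0, 256.0), radius_px=config.arena_radius / 0.02,
                         radius_mm=config.arena_radius)


def write_csv_tracks(
    labelled: LabelledTrajectory, path, arena: ArenaGeometry | None = None,
    track_id: int = 0,
) -> ArenaGeometry:
    """Write the generic CSV dialect ``frame,track_id,x_px,y_px``."""
    arena = arena or _default_arena(labelled.config)
    px = uncalibrate(labelled.trajectory, arena, track_id=track_id)
    px.to_csv(path, index=False)
    return arena

def write_toxtrac(
    labelled: LabelledTrajectory, path, arena: ArenaGeometry | None = None,
    track_id: int = 0, arena_id: int = 1,
) -> ArenaGeometry:
    """Write the ToxTrac-style dialect ``frame arena track x y``."""
    arena = arena or _default_arena(labelled.config)
    px = uncalibrate(labelled.trajectory, arena, track_id=track_id)
    df = pd.DataFrame(
        {
            "frame": px["frame"],
            "arena": arena_id,
            "track": px["track_id"],
            "x": px["x_px"],
            "y": px["y_px"],
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)
    return arena

def write_truth_modes(labelled: LabelledTrajectory, path) -> None:
    """Write the ground-truth regime index per frame (``frame,regime_index``)."""
    pd.DataFrame(
        {
            "frame": np.arange(labelled.trajectory.n_frames),
            "regime_index": labelled.true_modes,
        }
    ).to_csv(path, index=False)
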