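"""Local path complexity as positional entropy over sliding 3 s windows.

Within each window the trajectory is modelled as constant-velocity motion
(positions linear in time). The 2-D residuals around that fit capture how
unpredictable the movement is; their Gaussian differential entropy

    H = 1/2 * log2((2*pi*e)^2 * det(Sigma))   [bits]

is the local complexity at the window centre. A perfectly straight,
constant-speed trace has zero residuals and reports the floor entropy; a
tortuous trace with varying speeds and directions reports high entropy.

Numerics: the residual covariance eigenvalues are floored at ``floor_var``
(default 1 um^2) so the entropy of degenerate windows is finite; flooring
eigenvalues rather than axis variances keeps H invariant under rotation.
Residual variances use the regression dof correction (window length - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_io import Trajectory

__all__ = ["ComplexitySeries", "local_complexity", "min_complexity", "floor_entropy_bits"]

#: per-axis residual variance floor, um^2
FLOOR_VAR_UM2 = 1.0
#: default window length, s
WINDOW_S = 3.0

_LOG2_2PIE = float(np.log2(2 * np.pi * np.e))


def floor_entropy_bits(floor_var: float = FLOOR_VAR_UM2) -> float:
    """Entropy reported when both residual eigenvalues sit at the floor."""
    return _LOG2_2PIE + 0.5 * float(np.log2(floor_var * floor_var))


@dataclass
class ComplexitySeries:
    """Per-frame local complexity (NaN where the window is incomplete)."""

    H: np.ndarray          # bits
    window_s: float
    valid_mask: np.ndarray
    floor_bits: float

    def __post_init__(self) -> None:
        if len(self.H) != len(self.valid_mask):
            raise ValueError("H and valid_mask must have equal length")


def _centred_rolling_sum(a: np.ndarray, w: int) -> np.ndarray:
    """Sum of ``a`` over a centred window of odd length ``w`` ('same' edges)."""
    return np.convolve(a, np.ones(w), mode="same")


def local_complexity(
    traj: Trajectory, window: float = WINDOW_S, floor_var: float = FLOOR_VAR_UM2
) -> ComplexitySeries:
    """Positional-entropy series of one trajectory.

    The window is centred on each frame (odd length ``2h+1`` with
    ``h = floor(window*fps/2)``); windows that underrun the trace or
    overlap gaps are invalid. Residuals are measured in um so H is in bits
    relative to a 1 um^2 variance floor.
    """
    w0 = int(round(window * traj.fps))
    if w0 < 6:
        raise ValueError("window must span at least 6 frames")
    h = w0 // 2
    w = 2 * h + 1
    n = traj.n_frames
    if w > n:
        raise ValueError("window longer than trajectory")

    valid = (~traj.gap_mask) & np.isfinite(traj.x) & np.isfinite(traj.y)
    x = np.where(valid, traj.x, 0.0) * 1e3  # mm -> um
    y = np.where(valid, traj.y, 0.0) * 1e3
    # time index relative to window centre, in frames; only differences
    # matter for the residuals, so the regressor is k = -h..h
    idx = np.arange(n, dtype=float)

    cnt = _centred_rolling_sum(valid.astype(float), w)
    full = cnt >= w - 0.5  # exactly w valid frames in the window
    # rolling raw moments
    s_t = _centred_rolling_sum(np.where(valid, idx, 0.0), w)
    s_tt = _centred_rolling_sum(np.where(valid, idx * idx, 0.0), w)
    s_x = _centred_rolling_sum(x, w)
    s_y = _centred_rolling_sum(y, w)
    s_tx = _centred_rolling_sum(idx * x, w)
    s_ty = _centred_rolling_sum(idx * y, w)
    s_xx = _centred_rolling_sum(x * x, w)
    s_yy = _centred_rolling_sum(y * y, w)
    s_xy = _centred_rolling_sum(x * y, w)

    with np.errstate(invalid="ignore", divide="ignore"):
        m_t = s_t / w
        var_t = s_tt / w - m_t * m_t
        cov_tx = s_tx / w - m_t * (s_x / w)
        cov_ty = s_ty / w - m_t * (s_y / w)
        var_x = s_xx / w - (s_x / w) ** 2
        var_y = s_yy / w - (s_y / w) ** 2
        cov_xy = s_xy / w - (s_x / w) * (s_y / w)
        # residual (co)variances after removing the linear-in-time fit,
        # rescaled from ML (1/w) to the regression dof (w - 2)
        dof = w / (w - 2)
        rxx = (var_x - cov_tx**2 / var_t) * dof
        ryy = (var_y - cov_ty**2 / var_t) * dof
        rxy = (cov_xy - cov_tx * cov_ty / var_t) * dof
        # eigenvalues of the 2x2 residual covariance
        m = 0.5 * (rxx + ryy)
        d = np.sqrt(np.maximum(0.25 * (rxx - ryy) ** 2 + rxy**2, 0.0))
        lam1 = np.maximum(m + d, floor_var)
        lam2 = np.maximum(m - d, floor_var)
        H = _LOG2_2PIE + 0.5 * np.log2(lam1 * lam2)

    H = np.where(full, H, np.nan)
    return ComplexitySeries(
        H=H, window_s=w / traj.fps, valid_mask=full & np.isfinite(H),
        floor_bits=floor_entropy_bits(floor_var),
    )


def min_complexity(series: ComplexitySeries) -> float:
    """Minimal reached path complexity, bits."""
    if not series.valid_mask.any():
        raise ValueError("no valid complexity windows")
    return float(np.nanmin(series.H[series.valid_mask]))
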