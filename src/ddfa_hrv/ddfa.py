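"""Dynamical DFA: time- and scale-resolved scaling exponents alpha(t, s).

A sliding window of ``window_factor * s`` beats is moved along the recording
for every scale ``s`` of a logarithmic grid.  Inside each window the
fluctuation function is evaluated with *maximally overlapping* detrending
boxes (every beat offset), and the local exponent is the centered finite
difference of ``log F`` with respect to ``log s`` across the neighboring
grid scales.  Each window also carries its wall-clock center time and its
mean heart rate, so the landscape can later be aggregated over time
(``alpha(t, s)``) or over heart rate (``alpha(HR, s)``).

Implementation note: per-box squared residuals are computed once per scale
for *all* box offsets from a single globally detrended profile, using FFT
correlations with an orthonormal polynomial basis.  This is exact because
box-wise polynomial detrending of order >= 1 annihilates the affine offset
between a window-local profile and the global profile; window fluctuation
functions then reduce to moving averages of the per-box residuals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend
from scipy.signal import fftconvolve

from .dfa import DegenerateSeriesError, _box_basis
from .rri_io import RRISeries

__all__ = [
    "ScaleGrid",
    "DDFAConfig",
    "DDFALandscape",
    "make_scale_grid",
    "default_scale_grid",
    "ddfa_landscape",
    "landscape_to_long",
]


@dataclass(frozen=True)
class ScaleGrid:
    """Strictly increasing unique integer scales, approximately geometric."""

    scales: np.ndarray

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=int)
        object.__setattr__(self, "scales", scales)
        if scales.size < 2:
            raise ValueError("a scale grid needs at least 2 scales")
        if np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if scales[0] < 2:
            raise ValueError("scales must be >= 2")

    @property
    def count(self) -> int:
        return int(self.scales.size)

    def __len__(self) -> int:
        return self.count


def make_scale_grid(s_min: int = 5, s_max: int = 1000, count: int = 86) -> ScaleGrid:
    """Logarithmically spaced unique integer scales with exact endpoints.

    ``count`` geometric points are rounded to integers; collisions are then
    repaired by pushing values upward (and, near the top, downward) while
    preserving strict monotonicity and both endpoints exactly.
    """
    if s_min < 2 or s_max <= s_min or count < 2:
        raise ValueError("need s_min >= 2, s_max > s_min, count >= 2")
    if count > s_max - s_min + 1:
        raise ValueError(
            f"cannot place {count} unique integers in [{s_min}, {s_max}]"
        )
    vals = np.rint(np.geomspace(s_min, s_max, count)).astype(int)
    vals[0], vals[-1] = s_min, s_max
    for i in range(1, count):
        if vals[i] <= vals[i - 1]:
            vals[i] = vals[i - 1] + 1
    if vals[-1] != s_max:
        vals[-1] = s_max
        for i in range(count - 2, -1, -1):
            if vals[i] >= vals[i + 1]:
                vals[i] = vals[i + 1] - 1
    return ScaleGrid(scales=vals)


def default_scale_grid() -> ScaleGrid:
    """The default landscape grid: 86 log-spaced scales from 5 to 1000 beats."""
    return make_scale_grid(5, 1000, 86)


@dataclass(frozen=True)
class DDFAConfig:
    """Landscape-computation parameters.

    grid
        Scale grid (default 86 log scales, 5..1000).
    window_factor
        Window length as a multiple of the scale (window = window_factor * s
        beats); must be >= 2 so a window holds multiple boxes.
    order
        Detrending order (1 or 2).
    stride
        Beats between successive window placements; ``None`` means one tenth
        of the window length (at least 1 beat).
    centered
        If True the window timestamp is its wall-clock midpoint; if False the
        trailing edge (causal variant for on-line use).
    """

    grid: ScaleGrid = field(default_factory=default_scale_grid)
    window_factor: float = 5.0
    order: int = 2
    stride: Optional[int] = None
    centered: bool = True

    def __post_init__(self) -> None:
        if self.window_factor < 2:
            raise ValueError("window_factor must be >= 2")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class DDFALandscape:
    """alpha(t, s) over (window placement w, scale index j).

    Matrices are padded with NaN: scale ``j`` has ``n_windows[j]`` valid
    placements, and entries can additionally be NaN where the local
    fluctuation vanished.
    """

    alpha: np.ndarray  # (W_max, J)
    t: np.ndarray  # wall-clock window center, s
    hr: np.ndarray  # mean window heart rate, bpm
    scales: np.ndarray  # (J,)
    n_windows: np.ndarray  # valid placements per scale, (J,)

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.alpha)

    @property
    def n_defined(self) -> int:
        return int(np.count_nonzero(self.defined_mask))


def _box_mean_sq_residuals(y: np.ndarray, scale: int, order: int) -> np.ndarray:
    """Mean squared detrending residual of every length-``scale`` box.

    Returns an array of length ``len(y) - scale + 1``; entry ``i`` is the
    residual mean square of an order-``order`` polynomial fit on
    ``y[i : i + scale]``.
    """
    n = y.size
    s = int(scale)
    basis = _box_basis(s, order)
    csq = np.concatenate([[0.0], np.cumsum(y * y)])
    box_sumsq = csq[s:] - csq[:-s]
    proj_sq = np.zeros(n - s + 1)
    for c in range(basis.shape[1]):
        p = fftconvolve(y, basis[::-1, c], mode="valid")
        proj_sq += p * p
    return np.maximum(box_sumsq - proj_sq, 0.0) / s


def ddfa_landscape(
    series: RRISeries,
    config: Optional[DDFAConfig] = None,
    wall_times: Optional[np.ndarray] = None,
) -> DDFALandscape:
    """Compute the dynamical DFA landscape of a (filtered) RRI series.

    Parameters
    ----------
    series
        Artifact-filtered series; analysis runs on beat index.
    config
        Landscape parameters; defaults follow the module docstring.
    wall_times
        Original wall-clock beat times (s) for the time axis; defaults to
        ``series.times`` (re-accumulated time after filtering).
    """
    config = config or DDFAConfig()
    x = series.intervals
    n = x.size
    times = series.times if wall_times is None else np.asarray(wall_times, float)
    if times.size != n:
        raise ValueError("wall_times length must match the series")
    grid = config.grid.scales
    nj = grid.size

    window_len = np.rint(config.window_factor * grid).astype(int)
    feasible = np.flatnonzero((window_len <= n) & (grid >= config.order + 2))
    if feasible.size == 0:
        raise ValueError(
            f"recording of {n} beats too short for the smallest window "
            f"({window_len[0]} beats)"
        )

    # per-box residuals for every grid scale used by a feasible neighborhood
    needed = set()
    for j in feasible:
        needed.update({max(j - 1, 0), j, min(j + 1, nj - 1)})
    y = _linear_detrend(np.cumsum(x - x.mean()))
    e2_cum = {}
    for j in sorted(needed):
        e2 = _box_mean_sq_residuals(y, grid[j], config.order)
        e2_cum[j] = np.concatenate([[0.0], np.cumsum(e2)])

    cum_x = np.concatenate([[0.0], np.cumsum(x)])
    log_s = np.log(grid.astype(float))

    starts_per_scale, n_windows = {}, np.zeros(nj, dtype=int)
    for j in feasible:
        L = window_len[j]
        stride = config.stride if config.stride is not None else max(1, L // 10)
        starts = np.arange(0, n - L + 1, stride)
        starts_per_scale[j] = starts
        n_windows[j] = starts.size

    w_max = int(n_windows.max())
    alpha = np.full((w_max, nj), np.nan)
    t_mat = np.full((w_max, nj), np.nan)
    hr_mat = np.full((w_max, nj), np.nan)

    def _window_f2(j: int, starts: np.ndarray, L: int) -> np.ndarray:
        s = grid[j]
        span = L - s + 1
        c = e2_cum[j]
        return (c[starts + span] - c[starts]) / span

    for j in feasible:
        L = window_len[j]
        starts = starts_per_scale[j]
        jm = max(j - 1, 0)
        jp = min(j + 1, nj - 1)
        f2m = _window_f2(jm, starts, L)
        f2p = _window_f2(jp, starts, L)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (np.log(f2p) - np.log(f2m)) / (2.0 * (log_s[jp] - log_s[jm]))
        a[(f2m <= 0.0) | (f2p <= 0.0)] = np.nan
        k = starts.size
        alpha[:k, j] = a
        if config.centered:
            t_mat[:k, j] = 0.5 * (times[starts] + times[starts + L - 1])
        else:
            t_mat[:k, j] = times[starts + L - 1]
        hr_mat[:k, j] = 60000.0 * L / (cum_x[starts + L] - cum_x[starts])

    landscape = DDFALandscape(
        alpha=alpha, t=t_mat, hr=hr_mat, scales=grid, n_windows=n_windows
    )
    if landscape.n_defined == 0:
        raise DegenerateSeriesError(
            "no scaling exponent is defined anywhere (constant input?)"
        )
    return landscape


def landscape_to_long(landscape: DDFALandscape) -> pd.DataFrame:
    """Flatten defined landscape entries into rows (w, t_s, scale, hr_bpm, alpha)."""
    w_idx, j_idx = np.nonzero(landscape.defined_mask)
    return pd.DataFrame(
        {
            "w": w_idx,
            "t_s": landscape.t[w_idx, j_idx],
            "scale": landscape.scales[j_idx],
            "hr_bpm": landscape.hr[w_idx, j_idx],
            "alpha": landscape.alpha[w_idx, j_idx],
        }
    )
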