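"""Conventional whole-recording detrended fluctuation analysis (DFA).

DFA estimates the power-law correlation structure of a beat-indexed series:
the series is integrated into a profile, the profile is partitioned into
boxes of ``s`` beats, a polynomial trend of order ``m`` is removed in every
box, and the fluctuation function ``F(s)`` is the RMS residual.  The scaling
exponent ``alpha`` is the slope of ``log F`` versus ``log s``:

* ``alpha = 0.5`` — uncorrelated (white) noise,
* ``alpha = 1``   — 1/f-like long-range correlations,
* ``alpha < 0.5`` — anticorrelations (small and large intervals alternate).

Following common HRV practice, the exponent is reported in a short-scale
band ``alpha1`` (4–16 beats) and a long-scale band ``alpha2`` (16–64 beats),
for linear (DFA-1) or quadratic (DFA-2) detrending.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np

from .rri_io import RRISeries

__all__ = [
    "DFAConfig",
    "FluctuationFunction",
    "DFAResult",
    "DegenerateSeriesError",
    "profile",
    "fluctuation",
    "fluctuation_function",
    "fit_alpha",
    "dfa",
]


class DegenerateSeriesError(ValueError):
    """The input carries no fluctuations at the requested scales (F == 0)."""


def _default_scales() -> np.ndarray:
    return np.arange(4, 65)


@dataclass(frozen=True)
class DFAConfig:
    """Whole-recording DFA parameters.

    order
        Polynomial detrending order, 1 (DFA-1) or 2 (DFA-2).
    scales
        Integer box sizes at which F(s) is evaluated; default 4..64, which
        covers both fitting bands.
    band_alpha1, band_alpha2
        Closed scale intervals for the short- and long-scale exponent fits.
    """

    order: int = 2
    scales: np.ndarray = field(default_factory=_default_scales)
    band_alpha1: Tuple[int, int] = (4, 16)
    band_alpha2: Tuple[int, int] = (16, 64)

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=int)
        object.__setattr__(self, "scales", scales)
        if self.order not in (1, 2):
            raise ValueError("detrending order must be 1 or 2")
        if scales.size < 2 or np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be strictly increasing, >= 2 of them")
        if scales[0] < self.order + 2:
            raise ValueError(
                f"minimum scale {scales[0]} too small for order {self.order} "
                f"(need >= order + 2)"
            )
        for lo, hi in (self.band_alpha1, self.band_alpha2):
            if not (scales[0] <= lo < hi <= scales[-1]):
                raise ValueError(f"band ({lo}, {hi}) outside the scale range")


@dataclass(frozen=True)
class FluctuationFunction:
    """F(s) sampled on a set of integer scales."""

    scales: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=int))
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        if self.scales.size != self.F.size:
            raise ValueError("scales and F differ in length")
        if not np.all(np.isfinite(self.F)) or np.any(self.F < 0):
            raise ValueError("F must be finite and nonnegative")


@dataclass(frozen=True)
class DFAResult:
    alpha1: float
    alpha2: float
    order: int
    F: FluctuationFunction


def profile(intervals: Sequence[float]) -> np.ndarray:
    """Integrated, mean-centered profile ``y[k] = sum_{j<=k}(x_j - mean(x))``."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return np.cumsum(x - x.mean())


@lru_cache(maxsize=256)
def _box_basis(scale: int, order: int) -> np.ndarray:
    """Orthonormal polynomial basis (scale x (order+1)) over a box."""
    k = np.arange(scale, dtype=float)
    vander = np.vander(k, order + 1, increasing=True)
    q, _ = np.linalg.qr(vander)
    return q


def fluctuation(profile_y: np.ndarray, scale: int, order: int) -> float:
    """RMS detrending residual at one scale.

    The profile is partitioned into ``floor(N/s)`` non-overlapping boxes
    from the start *and* the same number from the end, so no samples are
    discarded when N is not a multiple of s.  Residuals are pooled over all
    ``2 * floor(N/s)`` boxes.
    """
    y = np.asarray(profile_y, dtype=float)
    n = y.size
    s = int(scale)
    if s < order + 2:
        raise ValueError(f"scale {s} too small for order {order}")
    if s > n:
        raise ValueError(f"scale {s} exceeds series length {n}")
    nb = n // s
    segments = np.concatenate(
        [y[: nb * s].reshape(nb, s), y[n - nb * s :].reshape(nb, s)]
    )
    basis = _box_basis(s, order)
    residuals = segments - (segments @ basis) @ basis.T
    return float(np.sqrt(np.mean(residuals**2)))


def fluctuation_function(
    profile_y: np.ndarray, scales: Sequence[int], order: int
) -> FluctuationFunction:
    scales = np.asarray(scales, dtype=int)
    F = np.array([fluctuation(profile_y, s, order) for s in scales])
    return FluctuationFunction(scales=scales, F=F)


def fit_alpha(F: FluctuationFunction, band: Tuple[float, float]) -> float:
    """Least-squares slope of ``log F`` vs ``log s`` inside a closed band."""
    lo, hi = band
    mask = (F.scales >= lo) & (F.scales <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError(f"fewer than 2 scales inside band {band}")
    if np.any(F.F[mask] == 0.0):
        raise DegenerateSeriesError(
            f"F(s) vanishes inside band {band}; the signal is degenerate"
        )
    slope, _ = np.polyfit(np.log(F.scales[mask]), np.log(F.F[mask]), 1)
    return float(slope)


def dfa(series: RRISeries | np.ndarray, config: Optional[DFAConfig] = None) -> DFAResult:
    """Whole-recording DFA of a (preferably artifact-filtered) RRI series.

    Operates on beat index — beats are treated as equidistant, the standard
    convention for RRI scaling analysis.
    """
    config = config or DFAConfig()
    intervals = series.intervals if isinstance(series, RRISeries) else np.asarray(series)
    if intervals.size < config.scales[-1]:
        raise ValueError(
            f"series of {intervals.size} beats shorter than the largest "
            f"scale {config.scales[-1]}"
        )
    y = profile(intervals)
    F = fluctuation_function(y, config.scales, config.order)
    return DFAResult(
        alpha1=fit_alpha(F, config.band_alpha1),
        alpha2=fit_alpha(F, config.band_alpha2),
        order=config.order,
        F=F,
    )
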