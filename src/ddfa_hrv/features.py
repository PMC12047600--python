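"""Classifier feature construction from per-subject surfaces.

The ``alpha(HR, s)`` surface is split at 100 bpm into a *rest* part
(HR < 100) and an *exercise* part (HR >= 100) so the two regimes can be
resized independently.  Empty (NaN) cells are imputed as 0 — the exponent
of a constant signal — and each part, together with the ``rho(alpha, s)``
density, is resized to a small X-by-Y image with bilinear interpolation.
Six summary heart-rate statistics of the filtered series complete the
fixed-length feature vector.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .aggregation import DensitySurface, HRSurface
from .rri_io import RRISeries

__all__ = [
    "HRStats",
    "FeatureConfig",
    "FeatureVector",
    "hr_stats",
    "impute_and_resize",
    "split_rest_exercise",
    "build_features",
    "feature_length",
    "minmax_fit_transform",
]


@dataclass(frozen=True)
class HRStats:
    """Summary statistics of the instantaneous heart rate (bpm)."""

    mean_hr: float
    sd_hr: float
    p1: float
    p25: float
    p75: float
    p99: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean_hr, self.sd_hr, self.p1, self.p25, self.p75, self.p99]
        )

    names = ("hr_mean", "hr_sd", "hr_p1", "hr_p25", "hr_p75", "hr_p99")


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-stage parameters.

    rest_exercise_split
        Heart-rate threshold (bpm) separating rest from exercise; must
        coincide with a surface bin edge (true for the default 1-bpm bins).
    rest_size, exercise_size, density_size
        Target (X, Y) image sizes for the three resized surfaces.
    include_hr_stats
        Whether the six heart-rate statistics are appended.
    """

    rest_exercise_split: float = 100.0
    rest_size: Tuple[int, int] = (8, 8)
    exercise_size: Tuple[int, int] = (8, 8)
    density_size: Tuple[int, int] = (8, 8)
    include_hr_stats: bool = True

    def __post_init__(self) -> None:
        for size in (self.rest_size, self.exercise_size, self.density_size):
            if size[0] < 2 or size[1] < 2:
                raise ValueError("resize targets must be at least 2x2")


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-length numeric features with aligned names."""

    values: np.ndarray
    names: Tuple[str, ...]
    subject_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size != len(self.names):
            raise ValueError("values and names differ in length")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")


def hr_stats(series: RRISeries) -> HRStats:
    """Mean, SD and percentiles of the per-beat heart rate 60000 / RRI.

    Percentiles use linear interpolation between order statistics; the SD is
    the sample standard deviation (ddof = 1).
    """
    if series.n_beats < 100:
        raise ValueError("need at least 100 beats for stable HR statistics")
    hr = 60000.0 / series.intervals
    p1, p25, p75, p99 = np.percentile(hr, [1, 25, 75, 99])
    return HRStats(
        mean_hr=float(hr.mean()),
        sd_hr=float(hr.std(ddof=1)),
        p1=float(p1), p25=float(p25), p75=float(p75), p99=float(p99),
    )


def _bilinear_resize(matrix: np.ndarray, size: Tuple[int, int]) -> np.ndarray:
    """Corner-aligned bilinear resampling of a 2-D array to ``size``."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D array")
    if m.shape[0] == 1:
        m = np.repeat(m, 2, axis=0)
    if m.shape[1] == 1:
        m = np.repeat(m, 2, axis=1)
    nx, ny = size
    interp = RegularGridInterpolator(
        (np.linspace(0.0, 1.0, m.shape[0]), np.linspace(0.0, 1.0, m.shape[1])),
        m, method="linear",
    )
    gx, gy = np.meshgrid(
        np.linspace(0.0, 1.0, nx), np.linspace(0.0, 1.0, ny), indexing="ij"
    )
    return interp(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(nx, ny)


def impute_and_resize(
    surface: Union[HRSurface, DensitySurface, np.ndarray], size: Tuple[int, int]
) -> np.ndarray:
    """Zero-impute undefined cells and bilinearly resize to ``size``.

    Zero is the exponent of a constant signal, so empty heart-rate or scale
    bins are treated as 'no variability there'.
    """
    if isinstance(surface, HRSurface):
        matrix = surface.alpha_mean
    elif isinstance(surface, DensitySurface):
        matrix = surface.rho
    else:
        matrix = np.asarray(surface, dtype=float)
    return _bilinear_resize(np.nan_to_num(matrix, nan=0.0), size)


def split_rest_exercise(
    surface: HRSurface, threshold: float = 100.0
) -> Tuple[HRSurface, HRSurface]:
    """Split an HR surface at a bin edge into rest (< threshold) and exercise."""
    edges = surface.hr_edges
    matches = np.isclose(edges, threshold)
    if not matches.any():
        raise ValueError(
            f"threshold {threshold} bpm does not coincide with a bin edge"
        )
    cut = int(np.flatnonzero(matches)[0])
    if cut == 0 or cut == edges.size - 1:
        raise ValueError("threshold must split the range into two nonempty parts")

    def _part(rows: slice, part_edges: np.ndarray) -> HRSurface:
        return HRSurface(
            alpha_mean=surface.alpha_mean[rows].copy(),
            counts=surface.counts[rows].copy(),
            hr_edges=part_edges.copy(),
            scales=surface.scales.copy(),
            dropped=np.zeros_like(surface.dropped),
        )

    return _part(slice(0, cut), edges[: cut + 1]), _part(slice(cut, None), edges[cut:])


def build_features(
    surface: HRSurface,
    density: DensitySurface,
    stats: Optional[HRStats],
    config: Optional[FeatureConfig] = None,
    subject_id: str = "",
) -> FeatureVector:
    """Assemble [resized rest | resized exercise | resized density | HR stats]."""
    config = config or FeatureConfig()
    if not np.array_equal(surface.scales, density.scales):
        raise ValueError("surface and density have mismatched scale grids")
    rest, exercise = split_rest_exercise(surface, config.rest_exercise_split)
    blocks = [
        ("rest", impute_and_resize(rest, config.rest_size)),
        ("exercise", impute_and_resize(exercise, config.exercise_size)),
        ("density", impute_and_resize(density, config.density_size)),
    ]
    values: List[float] = []
    names: List[str] = []
    for label, img in blocks:
        values.extend(img.ravel())
        names.extend(
            f"{label}[{i},{j}]"
            for i in range(img.shape[0])
            for j in range(img.shape[1])
        )
    if config.include_hr_stats:
        if stats is None:
            raise ValueError("config requests HR stats but none were given")
        values.extend(stats.as_array())
        names.extend(HRStats.names)
    return FeatureVector(
        values=np.asarray(values), names=tuple(names), subject_id=subject_id
    )


def feature_length(config: FeatureConfig) -> int:
    """Feature count implied by a config; independent of the data."""
    total = (
        config.rest_size[0] * config.rest_size[1]
        + config.exercise_size[0] * config.exercise_size[1]
        + config.density_size[0] * config.density_size[1]
    )
    return total + (6 if config.include_hr_stats else 0)


def minmax_fit_transform(
    train: Sequence[FeatureVector] | np.ndarray,
    apply_to: Optional[Sequence[FeatureVector] | np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min-max scale features, with ranges fitted on the training set only.

    Per feature: ``(x - min_train) / (max_train - min_train)``.  Zero-range
    features map to 0.  Values outside the training range are *not* clipped,
    so transformed test values may fall outside [0, 1].

    Returns ``(scaled, mins, maxs)`` where ``scaled`` corresponds to
    ``apply_to`` (or to ``train`` when ``apply_to`` is omitted).
    """

    def _matrix(vectors) -> np.ndarray:
        if isinstance(vectors, np.ndarray):
            return np.atleast_2d(np.asarray(vectors, dtype=float))
        return np.stack([v.values for v in vectors])

    x_train = _matrix(train)
    mins = x_train.min(axis=0)
    maxs = x_train.max(axis=0)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    x_apply = x_train if apply_to is None else _matrix(apply_to)
    return (x_apply - mins) / safe, mins, maxs
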