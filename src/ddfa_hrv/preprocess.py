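"""Statistical artifact filtering of RRI series.

Two rules, applied in order:

1. *Rolling-median rule*: a beat is kept iff its interval lies within
   ``[low_factor * eta, high_factor * eta]`` (bounds inclusive), where
   ``eta`` is the median of a centered window of ``kernel`` beats.
2. *Successive-difference rule*: a beat is removed iff its interval differs
   from the most recently kept interval by strictly more than
   ``diff_threshold`` milliseconds.

Both rules are purely statistical; no physiological beat classification
(ectopic / non-sinus labelling) is attempted, because non-sinus beats carry
condition-specific information the downstream analysis wants to keep.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .rri_io import Group, RRISeries, RRIValidationError

__all__ = [
    "FilterConfig",
    "FilterResult",
    "rolling_median",
    "median_filter",
    "diff_filter",
    "preprocess",
]


@dataclass(frozen=True)
class FilterConfig:
    """Artifact-filter parameters.

    kernel
        Rolling-median window length in beats (odd, >= 3).
    low_factor, high_factor
        Acceptance band around the local median.
    diff_threshold
        Maximum allowed jump between successive kept intervals, ms.
    """

    kernel: int = 31
    low_factor: float = 0.75
    high_factor: float = 1.5
    diff_threshold: float = 200.0

    def __post_init__(self) -> None:
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 3")
        if not (0.0 < self.low_factor < 1.0 < self.high_factor):
            raise ValueError("need 0 < low_factor < 1 < high_factor")
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be positive")


@dataclass(frozen=True)
class FilterResult:
    """Outcome of a filtering pass.

    ``kept_mask`` indexes the *input* series of the pass.  ``filtered`` has
    its time axis rebuilt by re-accumulating the surviving intervals (the
    downstream analysis runs in the beat domain); the original wall-clock
    times of the surviving beats are kept in ``wall_times`` for the
    time-resolved landscape axis.
    """

    kept_mask: np.ndarray
    n_removed_median: int
    n_removed_diff: int
    filtered: RRISeries
    wall_times: np.ndarray
    warning: bool = False

    @property
    def n_removed(self) -> int:
        return self.n_removed_median + self.n_removed_diff

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.kept_mask.size


def rolling_median(x: np.ndarray, kernel: int) -> np.ndarray:
    """Centered rolling median with symmetric window shrinkage at the edges.

    At position ``k`` the window is ``x[k-r : k+r+1]`` with
    ``r = min(kernel // 2, k, n - 1 - k)``, so the first and last beats use
    whatever symmetric neighborhood is available and the median is defined
    everywhere.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h = kernel // 2
    out = np.empty(n)
    if n >= kernel:
        windows = np.lib.stride_tricks.sliding_window_view(x, kernel)
        out[h : n - h] = np.median(windows, axis=1)
        edge = h
    else:
        edge = n  # window never fits: every position shrinks
    for k in range(min(edge, n)):
        r = min(h, k, n - 1 - k)
        out[k] = np.median(x[k - r : k + r + 1])
    for k in range(max(n - edge, 0), n):
        r = min(h, k, n - 1 - k)
        out[k] = np.median(x[k - r : k + r + 1])
    return out


def _rebuild(series: RRISeries, kept: np.ndarray) -> tuple:
    intervals = series.intervals[kept]
    if intervals.size < 2:
        raise RRIValidationError(
            f"{series.subject_id}: fewer than 2 beats survive filtering"
        )
    filtered = RRISeries(
        subject_id=series.subject_id,
        intervals=intervals,
        times=np.cumsum(intervals) / 1000.0,
        group=series.group,
        nyha=series.nyha,
        sr_fraction=series.sr_fraction,
    )
    return filtered, series.times[kept]


def median_filter(series: RRISeries, config: Optional[FilterConfig] = None) -> FilterResult:
    """Keep beat k iff ``low_factor*eta_k <= RRI_k <= high_factor*eta_k`` (inclusive)."""
    config = config or FilterConfig()
    x = series.intervals
    eta = rolling_median(x, config.kernel)
    kept = (x >= config.low_factor * eta) & (x <= config.high_factor * eta)
    filtered, wall = _rebuild(series, kept)
    n_rm = int(np.count_nonzero(~kept))
    return FilterResult(
        kept_mask=kept,
        n_removed_median=n_rm,
        n_removed_diff=0,
        filtered=filtered,
        wall_times=wall,
        warning=n_rm > 0.5 * x.size,
    )


def diff_filter(series: RRISeries, config: Optional[FilterConfig] = None) -> FilterResult:
    """Remove beats jumping > ``diff_threshold`` ms from the last kept beat.

    The first beat is always kept; each subsequent beat is compared against
    the most recent *kept* interval and removed on a strict exceedance.
    """
    config = config or FilterConfig()
    x = series.intervals
    kept = np.ones(x.size, dtype=bool)
    last = x[0]
    thr = config.diff_threshold
    for k in range(1, x.size):
        if abs(x[k] - last) > thr:
            kept[k] = False
        else:
            last = x[k]
    filtered, wall = _rebuild(series, kept)
    n_rm = int(np.count_nonzero(~kept))
    return FilterResult(
        kept_mask=kept,
        n_removed_median=0,
        n_removed_diff=n_rm,
        filtered=filtered,
        wall_times=wall,
        warning=n_rm > 0.5 * x.size,
    )


def preprocess(series: RRISeries, config: Optional[FilterConfig] = None) -> FilterResult:
    """Full artifact filter: rolling-median rule, then the difference rule.

    Returns a :class:`FilterResult` whose ``kept_mask`` indexes the original
    series.  The ``warning`` flag is raised when more than half of the beats
    were discarded — a data-quality signal, not an error.
    """
    config = config or FilterConfig()
    med = median_filter(series, config)
    dif = diff_filter(med.filtered, config)
    kept = med.kept_mask.copy()
    kept[np.flatnonzero(med.kept_mask)] = dif.kept_mask
    filtered, wall = _rebuild(series, kept)
    n_total_removed = int(np.count_nonzero(~kept))
    return FilterResult(
        kept_mask=kept,
        n_removed_median=med.n_removed_median,
        n_removed_diff=dif.n_removed_diff,
        filtered=filtered,
        wall_times=wall,
        warning=n_total_removed > 0.5 * series.n_beats,
    )
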