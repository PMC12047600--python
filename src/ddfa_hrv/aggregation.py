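"""Aggregation of DDFA landscapes into heart-rate and density surfaces.

Two per-subject summaries feed the group plots and the classifier:

* ``alpha(HR, s)`` — landscape entries grouped by the mean heart rate of
  their window, in 190 one-bpm bins spanning 30–220 bpm;
* ``rho(alpha, s)`` — per-scale normalized histogram of the exponent values
  over 50 uniform bins spanning 0–2.

Group aggregates average the *per-subject* surfaces bin by bin, so every
subject carries equal weight regardless of how many windows it contributed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .ddfa import DDFALandscape
from .rri_io import CohortManifest, Group, ManifestEntry

__all__ = [
    "HRSurface",
    "DensitySurface",
    "hr_surface",
    "density_surface",
    "group_surface",
    "split_subgroups",
]

HR_RANGE = (30.0, 220.0)
N_HR_BINS = 190
ALPHA_RANGE = (0.0, 2.0)
N_ALPHA_BINS = 50


@dataclass(frozen=True)
class HRSurface:
    """Mean exponent per (heart-rate bin, scale); NaN where no window fell.

    ``counts`` holds window counts for a per-subject surface and subject
    counts for a group surface.  ``dropped`` counts landscape entries per
    scale whose heart rate fell outside the binning range.
    """

    alpha_mean: np.ndarray  # (n_bins, J)
    counts: np.ndarray  # (n_bins, J)
    hr_edges: np.ndarray  # (n_bins + 1,)
    scales: np.ndarray  # (J,)
    dropped: np.ndarray  # (J,)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.hr_edges[:-1] + self.hr_edges[1:])


@dataclass(frozen=True)
class DensitySurface:
    """Per-scale normalized histogram of exponent values."""

    rho: np.ndarray  # (n_bins, J)
    alpha_edges: np.ndarray  # (n_bins + 1,)
    scales: np.ndarray  # (J,)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.alpha_edges[:-1] + self.alpha_edges[1:])


def hr_surface(
    landscape: DDFALandscape,
    n_bins: int = N_HR_BINS,
    hr_range: Tuple[float, float] = HR_RANGE,
) -> HRSurface:
    """Group landscape entries by window heart rate.

    Bins are half-open ``[lo, hi)`` with the final bin closed; entries
    outside the range are dropped and counted per scale in ``dropped``.
    """
    lo, hi = map(float, hr_range)
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins
    nj = landscape.scales.size
    sums = np.zeros((n_bins, nj))
    counts = np.zeros((n_bins, nj), dtype=int)
    dropped = np.zeros(nj, dtype=int)

    w_idx, j_idx = np.nonzero(landscape.defined_mask)
    hr = landscape.hr[w_idx, j_idx]
    av = landscape.alpha[w_idx, j_idx]
    bins = np.floor((hr - lo) / width).astype(int)
    bins[hr == hi] = n_bins - 1  # closed final bin
    in_range = (bins >= 0) & (bins < n_bins)
    np.add.at(sums, (bins[in_range], j_idx[in_range]), av[in_range])
    np.add.at(counts, (bins[in_range], j_idx[in_range]), 1)
    np.add.at(dropped, j_idx[~in_range], 1)

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HRSurface(
        alpha_mean=mean, counts=counts, hr_edges=edges,
        scales=landscape.scales.copy(), dropped=dropped,
    )


def density_surface(
    landscape: DDFALandscape,
    n_bins: int = N_ALPHA_BINS,
    alpha_range: Tuple[float, float] = ALPHA_RANGE,
) -> DensitySurface:
    """Per-scale histogram of exponent values, normalized to unit mass.

    Exponents outside ``alpha_range`` are excluded (not clipped); the range
    defines the histogram support.  Scales with no in-range data get an
    all-zero column.
    """
    lo, hi = map(float, alpha_range)
    edges = np.linspace(lo, hi, n_bins + 1)
    nj = landscape.scales.size
    rho = np.zeros((n_bins, nj))
    for j in range(nj):
        col = landscape.alpha[:, j]
        vals = col[np.isfinite(col)]
        vals = vals[(vals >= lo) & (vals <= hi)]
        if vals.size:
            hist, _ = np.histogram(vals, bins=edges)
            rho[:, j] = hist / hist.sum()
    return DensitySurface(rho=rho, alpha_edges=edges, scales=landscape.scales.copy())


def group_surface(surfaces: Sequence[HRSurface]) -> HRSurface:
    """Equal-weight aggregate of per-subject heart-rate surfaces.

    Each (bin, scale) cell is the mean over the *subjects* whose surface
    defines that cell — never a pool over windows — so subjects with long
    and short recordings count the same.  ``counts`` holds the number of
    contributing subjects per cell.
    """
    if not surfaces:
        raise ValueError("no surfaces to aggregate")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if not (
            np.array_equal(s.scales, ref.scales)
            and np.allclose(s.hr_edges, ref.hr_edges)
        ):
            raise ValueError("surfaces have mismatched binning or scales")
    stack = np.stack([s.alpha_mean for s in surfaces])
    defined = np.isfinite(stack)
    n_subj = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_subj > 0, np.nansum(np.where(defined, stack, 0.0), axis=0)
                        / np.maximum(n_subj, 1), np.nan)
    return HRSurface(
        alpha_mean=mean,
        counts=n_subj,
        hr_edges=ref.hr_edges.copy(),
        scales=ref.scales.copy(),
        dropped=np.sum([s.dropped for s in surfaces], axis=0),
    )


def split_subgroups(manifest: CohortManifest) -> Dict[str, List[ManifestEntry]]:
    """Partition CHF subjects by NYHA severity and AF subjects by SR fraction.

    CHF: mild (NYHA I–II) vs severe (NYHA III–IV).  AF: sinus-rhythm
    fraction > 0.80, in [0.01, 0.80], or < 0.01.  Subjects missing the
    relevant metadata land in an ``*_unknown`` stratum.
    """
    out: Dict[str, List[ManifestEntry]] = {
        "chf_mild": [], "chf_severe": [], "chf_unknown": [],
        "af_sr_gt80": [], "af_sr_1_80": [], "af_sr_lt1": [], "af_unknown": [],
    }
    for entry in manifest:
        if entry.group == Group.CHF:
            if entry.nyha in ("I", "II"):
                out["chf_mild"].append(entry)
            elif entry.nyha in ("III", "IV"):
                out["chf_severe"].append(entry)
            else:
                out["chf_unknown"].append(entry)
        elif entry.group == Group.AF:
            sr = entry.sr_fraction
            if sr is None:
                out["af_unknown"].append(entry)
            elif sr > 0.80:
                out["af_sr_gt80"].append(entry)
            elif sr >= 0.01:
                out["af_sr_1_80"].append(entry)
            else:
                out["af_sr_lt1"].append(entry)
    return out
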