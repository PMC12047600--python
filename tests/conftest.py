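"""Shared fixtures: small deterministic series and the synthetic study cohort."""
from __future__ import annotations

import numpy as np
import pytest

from ddfa_hrv import (
    RRISeries,
    build_features,
    ddfa_landscape,
    density_surface,
    gen_cohort,
    gen_scaling_noise,
    hr_stats,
    hr_surface,
    preprocess,
)

#: Cohort conditions for the end-to-end checks: 60 subjects per class with
#: ~2e4-beat recordings (a few hours of beats — enough for the full scale
#: grid while keeping the suite fast).
COHORT_SEED = 7
N_PER_CLASS = 60
N_BEATS = 20_000


def make_noise_series(alpha: float, n: int, seed: int, mean_ms: float = 800.0,
                      sd_ms: float = 40.0) -> RRISeries:
    """RRI series with a prescribed scaling exponent, for calibration tests."""
    x = gen_scaling_noise(alpha, n, seed=seed)
    return RRISeries.from_intervals(f"noise_a{alpha}_s{seed}", mean_ms + sd_ms * x)


@pytest.fixture(scope="session")
def study_cohort():
    """Fully processed synthetic cohort: features, labels and surfaces.

    Expensive (generates and analyzes 180 recordings), hence session scoped;
    only the end-to-end tests request it.
    """
    subjects, manifest = gen_cohort(
        (N_PER_CLASS, N_PER_CLASS, N_PER_CLASS), seed=COHORT_SEED, n_beats=N_BEATS
    )
    features, labels, surfaces = [], [], {"healthy": [], "chf": [], "af": []}
    for series in subjects:
        filt = preprocess(series)
        landscape = ddfa_landscape(filt.filtered, wall_times=filt.wall_times)
        surface = hr_surface(landscape)
        density = density_surface(landscape)
        stats = hr_stats(filt.filtered)
        vec = build_features(surface, density, stats, subject_id=series.subject_id)
        features.append(vec.values)
        labels.append(series.group.value)
        surfaces[series.group.value].append(surface)
    return {
        "X": np.stack(features),
        "labels": np.asarray(labels),
        "surfaces": surfaces,
        "manifest": manifest,
    }
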