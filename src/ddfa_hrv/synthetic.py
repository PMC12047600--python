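"""Synthetic RRI cohorts with group-specific correlation structure.

The generator produces labelled ~24-hour interbeat recordings whose
*statistical* signatures mirror what long-term Holter data show for the
three study groups, so the whole analysis chain can be exercised without
clinical recordings:

* **healthy** — strong short-scale correlations (target exponent ~1.3 below
  the crossover scale), a wide heart-rate range with a circadian swing;
* **CHF** — suppressed short-scale correlations (~0.85), reduced
  variability, and a capped maximum heart rate (beta-blockade-like);
* **AF** — alternating sinus-rhythm and fibrillation episodes; during
  episodes the intervals are nearly uncorrelated (exponent ~0.55) with
  strongly inflated variance.

Correlated noise is synthesized spectrally: random-phase inverse-Fourier
noise with power spectrum S(f) ~ f^(-beta) and beta = 2*alpha - 1, the
standard fGn correspondence between spectral slope and DFA exponent.  Short
and long-scale targets are realized by splicing two spectral slopes at a
crossover scale.  This is not a physiological cardiac model: only the
targeted statistical signatures are claimed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .rri_io import CohortManifest, Group, ManifestEntry, RRISeries

__all__ = [
    "ArchetypeParams",
    "default_params",
    "gen_scaling_noise",
    "gen_subject",
    "gen_cohort",
]


@dataclass(frozen=True)
class ArchetypeParams:
    """Generator parameters for one subject archetype.

    alpha_small / alpha_large
        Target scaling exponents below / above ``crossover_scale`` beats.
    mean_hr, hr_sd, circadian_amplitude, max_hr
        Heart-rate trajectory parameters in bpm; ``hr_sd`` scales the
        correlated beat-to-beat variability, ``max_hr`` caps the
        instantaneous rate.
    af_episode_fraction, af_alpha, af_var_inflation, af_hr_shift
        AF only: fraction of beats inside fibrillation episodes, the
        exponent and variance inflation of episode intervals, and the mean
        heart-rate shift during episodes.
    """

    group: Group
    n_beats: int = 100_000
    alpha_small: float = 1.3
    alpha_large: float = 1.0
    mean_hr: float = 80.0
    hr_sd: float = 5.0
    circadian_amplitude: float = 10.0
    max_hr: float = 190.0
    crossover_scale: float = 16.0
    af_episode_fraction: Optional[float] = None
    af_alpha: Optional[float] = None
    af_var_inflation: float = 4.0
    af_hr_shift: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_small", "alpha_large"):
            a = getattr(self, name)
            if not (0.0 < a < 2.0):
                raise ValueError(f"{name} must lie in (0, 2)")
        if self.mean_hr >= self.max_hr:
            raise ValueError("mean_hr must be below max_hr")
        if self.group != Group.AF and self.af_episode_fraction is not None:
            raise ValueError("af_episode_fraction is defined for the AF group only")
        if self.group == Group.AF:
            f = self.af_episode_fraction
            if f is None or not (0.0 <= f <= 1.0):
                raise ValueError("AF needs af_episode_fraction in [0, 1]")
            if self.af_alpha is None or not (0.0 < self.af_alpha < 2.0):
                raise ValueError("AF needs af_alpha in (0, 2)")


_GROUP_DEFAULTS: Dict[Group, dict] = {
    Group.HEALTHY: dict(
        alpha_small=1.3, alpha_large=1.0, mean_hr=80.0, hr_sd=5.0,
        circadian_amplitude=10.0, max_hr=190.0,
    ),
    Group.CHF: dict(
        alpha_small=0.85, alpha_large=1.1, mean_hr=90.0, hr_sd=2.0,
        circadian_amplitude=5.0, max_hr=130.0,
    ),
    Group.AF: dict(
        alpha_small=0.9, alpha_large=1.0, mean_hr=84.0, hr_sd=5.0,
        circadian_amplitude=8.0, max_hr=190.0,
        af_episode_fraction=0.5, af_alpha=0.55,
    ),
}


def default_params(group: Union[Group, str], **overrides) -> ArchetypeParams:
    """Archetype defaults for a group, with optional field overrides."""
    group = group if isinstance(group, Group) else Group.parse(group)
    if group not in _GROUP_DEFAULTS:
        raise ValueError(f"no generator archetype for group {group}")
    params = dict(_GROUP_DEFAULTS[group])
    params.update(overrides)
    return ArchetypeParams(group=group, **params)


def gen_scaling_noise(
    alpha_target: float,
    n: int,
    seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """Zero-mean unit-variance noise with DFA exponent ``alpha_target``.

    Random-phase inverse-Fourier synthesis with amplitude spectrum
    ``|f|^(-beta/2)``, ``beta = 2*alpha_target - 1``.
    """
    if not (0.0 < alpha_target < 2.0):
        raise ValueError("alpha_target must lie in (0, 2)")
    if n < 1024:
        raise ValueError("need n >= 1024 for a meaningful spectrum")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _spectral_noise(np.full(1, alpha_target), None, n, rng)


def _spectral_noise(
    alphas: np.ndarray,
    crossover_scale: Optional[float],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared synthesis core: one slope, or two slopes spliced at a crossover.

    ``alphas`` holds (alpha,) or (alpha_small, alpha_large); the crossover
    scale s_c maps to frequency 1 / (2 s_c).
    """
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(freqs.size)
    if alphas.size == 1:
        beta = 2.0 * alphas[0] - 1.0
        amp[1:] = freqs[1:] ** (-beta / 2.0)
    else:
        beta_small = 2.0 * alphas[0] - 1.0  # high-frequency branch
        beta_large = 2.0 * alphas[1] - 1.0  # low-frequency branch
        fc = 1.0 / (2.0 * crossover_scale)
        high = freqs >= fc
        amp[high] = freqs[high] ** (-beta_small / 2.0)
        low = (~high) & (freqs > 0)
        # continuous at fc
        scale = fc ** (-beta_small / 2.0) / fc ** (-beta_large / 2.0)
        amp[low] = scale * freqs[low] ** (-beta_large / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n)
    std = x.std()
    if std == 0:
        raise ValueError("degenerate spectrum")
    return (x - x.mean()) / std


def _episode_mask(
    n: int, fraction: float, rng: np.random.Generator, mean_block: int = 600
) -> np.ndarray:
    """Alternating SR/episode block mask hitting the target fraction exactly.

    Block lengths are drawn exponentially (discrete episode onsets) and each
    regime's lengths are rescaled so the realized fraction matches the
    request up to beat rounding.
    """
    target_ep = int(round(fraction * n))
    if target_ep <= 0:
        return np.zeros(n, dtype=bool)
    if target_ep >= n:
        return np.ones(n, dtype=bool)
    target_sr = n - target_ep

    def _blocks(total: int) -> np.ndarray:
        k = max(1, int(round(total / mean_block)))
        raw = rng.exponential(1.0, k)
        lens = np.maximum(1, np.rint(raw / raw.sum() * total)).astype(int)
        lens[-1] += total - lens.sum()
        if lens[-1] < 1:  # borrow from the largest block
            deficit = 1 - lens[-1]
            lens[np.argmax(lens)] -= deficit
            lens[-1] = 1
        return lens

    ep_lens, sr_lens = _blocks(target_ep), _blocks(target_sr)
    mask = np.zeros(n, dtype=bool)
    pos, ei, si, in_ep = 0, 0, 0, bool(rng.integers(2))
    while pos < n:
        if in_ep and ei < ep_lens.size:
            mask[pos : pos + ep_lens[ei]] = True
            pos += ep_lens[ei]
            ei += 1
        elif not in_ep and si < sr_lens.size:
            pos += sr_lens[si]
            si += 1
        elif ei < ep_lens.size:
            in_ep = True
            continue
        elif si < sr_lens.size:
            in_ep = False
            continue
        else:
            break
        in_ep = not in_ep
    return mask


def gen_subject(params: ArchetypeParams, subject_id: Optional[str] = None) -> RRISeries:
    """Generate one synthetic subject's RRI series from its archetype.

    The heart-rate trajectory is mean + circadian sinusoid + slow drift,
    modulated by spliced-spectrum scaling noise scaled to ``hr_sd`` and
    clipped at ``max_hr``; intervals are ``60000 / HR``.  AF subjects embed
    fibrillation episodes with their own exponent, inflated variance and a
    small positive rate shift.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_beats
    k = np.arange(n)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    circadian = params.circadian_amplitude * np.sin(2.0 * np.pi * k / n + phase)
    drift = gaussian_filter1d(rng.standard_normal(n), sigma=max(n / 100.0, 2.0))
    drift_std = drift.std()
    if drift_std > 0:
        drift *= 0.5 * params.circadian_amplitude / drift_std
    hr_base = params.mean_hr + circadian + drift

    noise = _spectral_noise(
        np.array([params.alpha_small, params.alpha_large]),
        params.crossover_scale, n, rng,
    )
    hr = hr_base + params.hr_sd * noise

    sr_fraction = None
    if params.group == Group.AF:
        mask = _episode_mask(n, params.af_episode_fraction, rng)
        noise_af = _spectral_noise(np.full(1, params.af_alpha), None, n, rng)
        hr_af = (
            hr_base + params.af_hr_shift
            + params.hr_sd * params.af_var_inflation * noise_af
        )
        hr = np.where(mask, hr_af, hr)
        sr_fraction = 1.0 - float(np.count_nonzero(mask)) / n

    hr = np.clip(hr, 32.0, params.max_hr)
    intervals = 60000.0 / hr
    return RRISeries.from_intervals(
        subject_id=subject_id or f"{params.group.value}_{params.seed}",
        intervals=intervals,
        group=params.group,
        sr_fraction=sr_fraction,
    )


def gen_cohort(
    n_per_group: Union[Tuple[int, int, int], Dict[Union[Group, str], int]],
    seed: int = 0,
    n_beats: int = 100_000,
    jitter: bool = True,
) -> Tuple[list, CohortManifest]:
    """Generate an independent labelled cohort.

    Parameters
    ----------
    n_per_group
        ``(n_healthy, n_chf, n_af)`` or a mapping from group to count.
    seed
        Master seed; every subject receives an independently derived seed.
    n_beats
        Beats per subject (~1e5 corresponds to 24 h).
    jitter
        Randomize archetype parameters per subject (heart-rate level,
        exponents, variability, AF episode load) to create within-group
        spread; with ``False`` every subject uses the archetype defaults.

    Returns
    -------
    (subjects, manifest)
        AF subjects carry ``sr_fraction``; CHF subjects get randomized NYHA
        labels so severity subgrouping is exercisable.
    """
    if isinstance(n_per_group, dict):
        counts = {
            (g if isinstance(g, Group) else Group.parse(g)): int(c)
            for g, c in n_per_group.items()
        }
    else:
        counts = dict(zip((Group.HEALTHY, Group.CHF, Group.AF), map(int, n_per_group)))
    master = np.random.default_rng(seed)
    subjects, entries = [], []
    for group in (Group.HEALTHY, Group.CHF, Group.AF):
        for i in range(counts.get(group, 0)):
            child_seed = int(master.integers(0, 2**31 - 1))
            overrides: dict = {"n_beats": n_beats, "seed": child_seed}
            nyha = None
            if jitter:
                overrides["mean_hr"] = _GROUP_DEFAULTS[group]["mean_hr"] + float(
                    master.normal(0.0, 4.0)
                )
                overrides["alpha_small"] = float(
                    np.clip(
                        _GROUP_DEFAULTS[group]["alpha_small"] + master.normal(0.0, 0.05),
                        0.1, 1.9,
                    )
                )
                overrides["hr_sd"] = _GROUP_DEFAULTS[group]["hr_sd"] * float(
                    master.lognormal(0.0, 0.15)
                )
            if group == Group.AF:
                sr = float(master.uniform(0.0, 0.95)) if jitter else 0.5
                overrides["af_episode_fraction"] = 1.0 - sr
            if group == Group.CHF:
                nyha = str(master.choice(["I", "II", "III", "IV"]))
            subject_id = f"{group.value}_{i:03d}"
            series = gen_subject(default_params(group, **overrides), subject_id)
            series = series.with_metadata(nyha=nyha)
            subjects.append(series)
            entries.append(
                ManifestEntry(
                    path=f"{subject_id}.rri",
                    subject_id=subject_id,
                    group=group,
                    nyha=nyha,
                    sr_fraction=series.sr_fraction,
                )
            )
    return subjects, CohortManifest(entries=entries)
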