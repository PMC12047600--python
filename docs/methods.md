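# Methods

This note records what the package computes, the defaults it ships with,
and the choices made where the procedure admits more than one reasonable
implementation. Nothing here states a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Artifact filtering

Long-term RRI recordings contain missed or spurious beat detections. Two
purely statistical rules are applied in order:

1. **Rolling-median rule.** Beat *k* is kept iff
   `0.75·η_k ≤ RRI_k ≤ 1.5·η_k` (bounds inclusive), where `η_k` is the
   median of a 31-beat window centered on *k*. At the series edges the
   window shrinks symmetrically (`x[k−r : k+r+1]`, `r = min(15, k, n−1−k)`)
   so `η` is defined everywhere and edge beats are not discarded wholesale.
   `η` is computed once on the raw series — the rule is a single pass, not
   an iteration to a fixed point.
2. **Successive-difference rule.** A beat is removed iff its interval
   differs by strictly more than 200 ms from the most recently *kept*
   interval; the first beat is always kept; the later beat of an offending
   pair is the one removed. These three conventions (strict inequality,
   compare-to-last-kept, remove-the-later) are implementation choices the
   rule statement itself leaves open.

No physiological beat classification is attempted: non-sinus beats carry
condition-specific information downstream stages want to keep.

After filtering, the beat-domain time axis is rebuilt by re-accumulating
the surviving intervals (all scaling analysis runs on beat index); the
original wall-clock times of the surviving beats are retained separately
and provide the time axis of the dynamical landscape.

Two properties worth knowing:

* The combined filter is **idempotent on realistic data** (a second pass
  removes nothing) but **not monotone** under loosening: widening the
  median band can keep an artifact that then triggers extra removals in the
  sequential difference rule. Monotonicity holds per rule — provably for
  the median rule, and for the difference rule in the isolated-spike regime
  typical of ectopy. The tests assert exactly that.
* The compare-to-last-kept convention makes the filter sensitive to an
  artifact in the very first beat (the anchor is never revised). Recordings
  should not begin mid-artifact; the quality flag (below) catches the
  pathological cases.

A result whose removal fraction exceeds 50% carries a `warning` flag; the
pipeline excludes such subjects with a logged reason rather than failing.

## Whole-recording DFA

Standard estimator: mean-centered cumulative profile, non-overlapping boxes
of *s* beats taken from **both ends** of the series (`2·⌊N/s⌋` boxes, so no
samples are discarded when `s ∤ N`), least-squares polynomial detrending of
order 1 or 2 per box, `F(s)` = RMS residual pooled over all boxes.
Exponents are least-squares slopes of `log F` vs `log s` (natural log;
the slope is base-invariant) over the closed bands 4–16 (`alpha1`) and
16–64 (`alpha2`), evaluated at all integer scales 4–64. `F(s) = 0` inside a
fitting band (constant input) raises a degeneracy error rather than
producing a fake exponent.

Calibration, recomputed by the tests and the acceptance script: 50 i.i.d.
Gaussian series of 20 000 beats give mean DFA-1 `alpha2` within 0.5 ± 0.05,
and spectral noise with targets {0.5, 0.75, 1.0, 1.25, 1.5} is recovered by
DFA-2 within ±0.1 (mean of 20 replicates each).

## Dynamical DFA

The local exponent `alpha(t, s)` is estimated on 86 logarithmically spaced
integer scales from 5 to 1000 beats. The integer grid is built by rounding
86 geometric points and repairing collisions upward while keeping both
endpoints exact; with these parameters the grid is collision-free at the
top and consecutive-integer at the bottom.

Per scale *s*:

* window length `5·s` beats, advanced by one tenth of the window (≥ 1
  beat). The window factor and stride are free parameters of the method;
  5 and 1/10 are this package's defaults, chosen as a compromise between
  estimator variance (longer windows) and time resolution (shorter ones).
  Because downstream results are aggregates over many windows, the stride
  mainly affects variance, not bias.
* inside each window the fluctuation function uses **maximally
  overlapping** boxes (every beat offset), which stabilizes `F` in windows
  that hold only a handful of disjoint boxes;
* `alpha` is the centered finite difference of `log F` with respect to
  `log s` across the two neighboring grid scales (one-sided at the grid
  ends) — a local slope, not a band fit;
* each window records its wall-clock midpoint (a trailing-edge variant is
  available for causal/on-line use) and its mean heart rate
  `60000 / mean(RRI)`.

Windows that do not fit the recording are not emitted; vanishing `F`
yields an undefined (NaN) entry. Undefined entries propagate explicitly —
zero-imputation happens only at the feature stage.

**Implementation.** Residuals are computed once per scale for *all* box
offsets from a single global profile, as
`‖y_box‖² − Σ_c (q_c·y_box)²` with an orthonormal polynomial basis `q_c`,
evaluated for every offset by FFT correlation; window fluctuation functions
are then moving averages of these per-box residuals. This is exact, not an
approximation: polynomial detrending of order ≥ 1 inside a box annihilates
the affine offset between a window-local profile and the global profile.
The global profile is linearly detrended first to reduce floating-point
cancellation in the subtraction. A 20 000-beat recording over the full
grid takes well under a second; the estimator is validated against a naive
per-box `polyfit` oracle at 1e-10 relative tolerance.

## Aggregation

* `alpha(HR, s)`: 190 half-open one-bpm bins on [30, 220) (final bin
  closed), mean exponent and window count per (bin, scale); entries outside
  the range are dropped and counted per scale, so bin counts + dropped
  counts exactly conserve the number of defined landscape entries.
* `rho(alpha, s)`: per-scale histogram over 50 uniform bins on [0, 2],
  normalized to unit mass; exponents outside [0, 2] are **excluded, not
  clipped** — the range defines the histogram support.
* Group aggregates average **per-subject surfaces** cell-wise over the
  subjects that define each cell, never pooling windows, so every subject
  carries equal weight regardless of recording length.
* Subgroup splits: CHF by NYHA class (I–II mild vs III–IV severe); AF by
  sinus-rhythm fraction (> 0.80, 0.01–0.80, < 0.01). Subjects missing the
  metadata land in explicit `*_unknown` strata.

## Features and classification

Feature vector = [resized rest `alpha(HR, s)` | resized exercise
`alpha(HR, s)` | resized `rho(alpha, s)` | 6 HR statistics], with the
rest/exercise split at the 100 bpm bin edge (70 and 120 bins). Undefined
surface cells are imputed as 0 — the exponent of a constant signal — before
corner-aligned bilinear resizing. Default image size is 8×8 per block
(198 features); the resize sizes are legitimate hyperparameters and can be
grid-searched per fold (features are rebuilt per candidate). HR statistics
are mean, sample SD (ddof = 1) and the 1st/25th/75th/99th percentiles of
the per-beat rate `60000 / RRI`, with linear interpolation between order
statistics.

Min-max scaling maps each feature's training minimum/maximum to 0/1;
zero-range features map to 0; test values are deliberately **not clipped**,
so out-of-range test data remains visible to the model.

The classifier pipeline is min-max scaling → PCA → XGBoost, all fitted
inside the training data of each split. Nested cross-validation uses 10
outer *repeated stratified* 50/50 train/test splits (10 disjoint test sets
of half the cohort each cannot exist, so repeats are the only reading
consistent with the stated fold count and test size) and 10-fold stratified
grid search inside each training half, selecting on mean balanced accuracy
(robust to class imbalance). Default grid: PCA components {10, 20, 50},
trees {100, 300}, depth {2, 4, 6}, learning rate {0.05, 0.1}. Multiclass
uses a single multinomial ensemble, not one-vs-rest. XGBoost runs with
`tree_method="exact"`: at cohort-sized n the histogram method places split
thresholds flush against a training sample (zero margin), which needlessly
misclassifies boundary test points; exact splits sit mid-gap.

Binary tasks report sensitivity and specificity for the declared positive
class; all tasks report balanced accuracy (mean per-class recall, empty
classes excluded with a warning) per fold, as mean ± SD over folds, and as
an aggregate row-normalized confusion matrix. ROC AUC uncertainty uses
DeLong's structural-components variance with ties counted 1/2; the
estimator is tested to agree exactly with brute-force pairwise counting.

## Synthetic cohort generator

The generator exists so every stage — including the classifier — can be
exercised on data with *known* ground truth. It is a statistical emulator,
not a cardiac model: it targets the correlation and heart-rate signatures
that distinguish the three groups in long-term recordings, and claims
nothing else.

Correlated noise is synthesized by random-phase inverse-Fourier synthesis
with power spectrum `S(f) ∝ f^(−β)`, `β = 2·alpha − 1` (the standard
fractional-Gaussian-noise correspondence between spectral slope and DFA
exponent). Short- and long-scale targets are realized by splicing two
spectral slopes continuously at the frequency `1/(2·s_c)` of a crossover
scale (default `s_c = 16`, the `alpha1`/`alpha2` boundary).

Archetype defaults (per-subject jitter is applied in cohorts):

| group | alpha_small | alpha_large | mean HR | HR sd | circadian | max HR | episodes |
| --- | --- | --- | --- | --- | --- | --- | --- |
| healthy | 1.3 | 1.0 | 80 | 5 | 10 | 190 | — |
| CHF | 0.85 | 1.1 | 90 | 2 | 5 | 130 | — |
| AF | 0.9 (SR) | 1.0 | 84 | 5 | 8 | 190 | alpha 0.55, variance ×4, +8 bpm |

Units: bpm throughout; `circadian` is the amplitude of a one-cycle
sinusoid over the recording, supplemented by a smoothed random drift, so
`alpha(HR, s)` has non-degenerate support across HR bins. The heart-rate
trajectory is clipped at `max HR` — for CHF this emulates the absence of
high rates (beta-blockade-like) with correspondingly suppressed
variability. AF recordings alternate sinus-rhythm and episode blocks with
exponentially distributed lengths (mean 600 beats), rescaled so the
realized episode fraction matches the request up to beat rounding; the
sinus-rhythm fraction is stored as subject metadata. Exponent and
heart-rate levels were fixed from the qualitative group signatures the
method is known to resolve (healthy ≈ 1.2–1.4 at small scales and low HR,
CHF ≈ 0.7–1.0 with suppressed HR range, AF low-exponent episodes over a
wide scale range); parameters beyond those bands are free choices and the
cohort is **not** a quantitative reproduction of any clinical population.

What the generator deliberately does not emulate: ectopy and detector
artifacts (tests inject those separately), respiratory sinus arrhythmia,
realistic activity bursts, medication effects, inter-database heterogeneity.
Consequently, passing end-to-end tests demonstrates that the chain
*recovers structure it is designed to measure* and that the classifier
separates groups whose generative signatures differ as described — it does
not certify clinical accuracy on real recordings.

## Problem sizes and runtime choices

The test suite runs the full chain at 60 subjects per class with 20 000
beats per recording (a few hours of beats — long enough to populate the
full scale grid), with a reduced hyperparameter grid (PCA {10, 20}, depth
{2, 4}, 100 trees, learning rate 0.1) for the cohort evaluation; the
permutation-null check reuses the same features with shuffled labels and a
single-candidate grid. Generator defaults are ~10⁵ beats (24 h). The
acceptance script's calibration uses 50 replicates of 20 000 beats.

## Numerical details

* Degenerate inputs raise (`DegenerateSeriesError`) rather than returning
  silent zeros: constant series in DFA, landscapes with no defined entry.
* Grid-search ties break toward the first candidate in iteration order;
  candidate order is deterministic (sorted parameter names).
* All randomness flows from explicit integer seeds: cohort generation
  derives per-subject seeds from a master generator; CV splits and model
  fits take the CV seed. Reports record the seed; reruns with identical
  inputs and config are byte-identical (landscapes are content-hash cached).
* Cumulative-time consistency in files is checked to 1 ms (text rounding);
  interval round-trips are exact to better than 1e-6 ms.

## Known limitations

* The DDFA windowing (window factor, stride, finite-difference
  neighborhood) follows this package's documented defaults; other
  implementations of time-resolved DFA may make different choices, so
  landscape values are comparable across packages only qualitatively.
* R-peak detection from raw ECG is out of scope; inputs are interval
  series (plain text, CSV, or WFDB annotations via the optional extra).
* The multivariable confounder regression and reproduction of
  clinical-database classification accuracies are out of scope; the
  classifier here is validated on synthetic cohorts only.
* `alpha(t, s)` windows are beat-domain; wall-clock timestamps are carried
  through for display and aggregation but windows are not resampled to
  uniform time.
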