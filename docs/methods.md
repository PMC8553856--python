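# Methods

This note documents the models, conventions and design choices behind
`overlapmaps`: what the synthetic generator emulates, what each analysis
computes, the numerical conventions, and the limits of what passing tests
demonstrate about real data.

## Design model

The environment is three cities over one circular layout: six peripheral
slots on a circle (regular hexagon, configurable radius, default 1.0 length
unit, center store at the origin) and a fixed store-to-slot map.  City
store sets are `{1..6}`, `{1,2,3,5,6,7}` and `{1,3,5,7,8,9}`; overlaps are
5/4/3 stores between city pairs and `{1,3,5}` across all three.  Travel
durations from the center are 8 s for stores {3,5,6,9} and 16 s for
{1,2,4,7,8}.  Store coordinates are not tabulated anywhere authoritative,
so the regular hexagon is a package choice; it lives in the environment
config so every geometric quantity (including the enumeration of distinct
distance-index values — five on this layout) can be recomputed under
alternative layouts.

Retrieval schedules comprise 12 runs × 15 trials (six consecutive runs per
task, two per city), with city order pseudorandomized under two
constraints: no city twice in a row, and every city tested once before any
repeat.  Trials last 18.13 s (9 s triad display, 7.77 s active baseline,
1.36 s gap).  Per task, 60% of trials are unequal comparisons and 40%
equal; a spatial triad is "equal" when its two top-to-bottom distances tie
within 1e-9 length units.  Temporal runs present all C(6,2) = 15 bottom-store
pairs of the city exactly once, which reproduces the 60:40 split identically;
spatial runs sample triads under the equal/unequal quota.  Because the exact
trial lists are a free design dimension, every spatial run also includes
anchor triads — the tri-city set {1,3,5}, the city-1/2 set {2,3,6}, the
city-2/3 set {3,5,7}, and one set unique to the run's city (pairwise
disjoint across cities) — so all between-city pair conditions are populated
under any seed.  Correctness and motion-censoring flags are Bernoulli draws
(defaults 0.9 and 0.05) when patterns are simulated directly; the BOLD path
derives censoring from a simulated framewise-displacement trace at the
0.5 mm threshold.

The localizer is 2 runs × 18 trials: each of the six studied stores
{2,4,6,7,8,9} appears three times per run, once per triad position, flanked
by unstudied filler stores, with inter-repetition gaps of 2–12 trials.

## Synthetic data generator

Each effect the analyses test is planted as an explicit latent construction
over `n_neurons` (default 200) latent units, mixed into `n_voxels` (default
100) voxels by a nonnegative pooling matrix (each voxel pools 12 random
neurons with gamma weights, L2-normalized).  The defaults are desk-scale:
large enough for stable statistics, small enough that multi-hundred-subject
recovery sweeps run in minutes on one CPU.

* Store codes are drawn from an orthonormal basis constructed orthogonal to
  the constant vector, so distinct stores are *exactly* orthogonal and
  sample Pearson correlations equal their construction Gram matrix exactly.
  A store shared by k cities gets k vectors with pairwise correlation
  exactly `rho_shared` via an eigenvalue square root of the equicorrelation
  matrix (achievable for rho ≥ −1/(k−1); the generator rejects anything
  lower).  This removes Monte-Carlo slack from recovery tests.
* A trial's neuron signal sums: presented-store codes (per city), plus
  `eta_holistic ×` the city's unpresented unique-store codes, plus
  `gamma_city ×` a city code, plus `beta_schema × D` along a schema
  direction (spatial trials), plus `beta_slot ×` codes of the occupied
  layout slots, plus `kappa_interval ×` an interval-category code (shared
  across cities or city-specific).
* The center store appears in every temporal trial of every city, so its
  identity code is a task-common component carrying no trial-discriminative
  information; its amplitude defaults to 0 (`center_amplitude`).  With a
  nonzero amplitude it inflates all temporal-pair correlations equally in
  principle, but the between-city conditions contain different fractions of
  temporal pairs, which would bias their contrast — a perceptual confound
  the analyses are not designed to measure.
* Noise is i.i.d. Gaussian per voxel with SD `sigma_noise × tsnr_median /
  tsnr_v`; per-voxel tSNR is lognormal (median 40, log-SD 0.3).  This is the
  simplest model under which the eight-level tSNR filter is consequential.
  Default `sigma_noise` = 1.0 puts single-pair correlations in the weak
  (|r| ~ 0.1–0.3) regime typical of single-trial fMRI patterns.
* The BOLD path convolves trial boxcars with a double-gamma HRF (SPM
  variant), scales by the trial's voxel amplitudes, and adds AR(1) noise
  (TR 2.59 s, AR coefficient 0.3).  Framewise displacement is a baseline
  of 0.05 mm with i.i.d. spikes; trials overlapping any frame above 0.5 mm
  are censored.
* All randomness flows from one root seed through named substreams
  (`numpy` SeedSequence spawn keys), so every stage is reproducible
  bit-for-bit.

What the generator does *not* emulate: spatial autocorrelation of voxel
noise, physiological noise, scanner drift beyond the AR(1) term, realistic
hemodynamic variability, behavioral response dynamics, or semantic
relationships between stores.  Recovery results therefore show that the
*statistics* are correct and well-calibrated under their own assumptions,
not that real hippocampal data would yield the same effect sizes.

## Single-trial and run-level GLMs

LS-S: one GLM per trial with the trial of interest and all remaining trials
as two HRF-convolved regressors, plus optional motion columns, one
unit-impulse column per flagged outlier frame, discrete-cosine high-pass
drift regressors (100 s cutoff; the GLM-equivalent of the nonlinear
high-pass commonly applied in preprocessing) and an intercept.  The
per-voxel t statistic (OLS β / SE) is the trial's pattern value; OLS rather
than prewhitened variance is used (flag-able choice; the two coincide as
AR noise → white).  Correct active-baseline periods are left unmodeled as
implicit baseline.  Rank-deficient designs fail loudly, naming the most
collinear column pair.  Run-level maps use a remembered-trials regressor
(correct ∧ uncensored) with the remaining trials pooled.

With 18.13 s trials the LS-S and full-model estimates agree closely and
converge as spacing grows (verified against the closed-form OLS oracle);
at this spacing the residual approximation error is the cost of the LS-S
variance reduction.

## Voxel quality (tSNR)

tSNR = time-series mean / sample SD (ddof = 1); zero-variance voxels are
excluded with a warning.  Masks at the 10th–80th percentiles remove voxels
strictly below the level's percentile (numpy linear interpolation); ties
are kept, so the eight kept-sets are nested and an all-equal ROI loses
nothing.  The percentile/SD/tie conventions are exposed because no single
convention is canonical.  Pattern-similarity statistics are computed per
level and averaged across the eight levels ("averaged across 8 tSNRs").

## Pattern-similarity conventions

Pearson r between voxel vectors after per-pattern mean removal only (no
z-scoring — a config choice), Fisher-z (atanh) per pair, mean within
condition, grand mean across tSNR levels last.  |r| is clamped at
1 − 1e−12 before atanh.  Zero-variance patterns drop their pairs, which are
counted and reported.  Incorrect and censored trials never pair.

Between-city pair rules operate on *peripheral* store sets (the center
store belongs to every city and is ignored, matching how city overlap is
counted): unique-trial pairs require disjoint sets (a clean baseline of
unrelated content), two-/three-shared pairs require identical sets
presented in runs of different cities.  Since each run probes one city,
between-city pairs are automatically cross-run, avoiding within-run
autocorrelation.  Cross-task pairs are included by default (flag to
restrict).  The same-location searchlight statistic compares identical
slot-set pairs with different-slot pairs matched on (triad size, number of
differing store identities); strata with no matched different-location
pair are dropped and reported.

## Decoding

* **Distance SVR** — linear kernel, C = 1, ε = 0.1 (unstated
  hyperparameters fixed at library defaults, exposed in the signature);
  optional feature standardization off by default.  Before decoding, trials
  are trimmed to a uniform distance-frequency distribution: while a KS test
  against the discrete uniform over the distance bins rejects at α = 0.05,
  one seeded-random trial is removed from the over-full bin (ties toward
  the shortest distance, the bin that over-fills under this design).  The
  KS reference is the discrete uniform over observed bins by default; the
  design's full bin set can be supplied.  Accuracy is Fisher-z Spearman ρ
  (actual vs predicted) per held-out city, averaged over the three folds;
  chance 0.  Because the hexagon layout admits only five distinct distance
  values, actual distances are heavily tied and fold-level ρ saturates
  slightly below 1 even for a noiseless code.
* **Interval SVM** — 3-class linear SVM (16/24/32 s), leave-one-city-out,
  class counts balanced by seeded subsampling in both training and test
  sets; chance 1/3.
* **City SVM** — linear SVM, C = 1, on the 12 run-level maps.  The number
  of leave-three-runs-out iterations is open in principle; all 64
  one-run-per-city combinations are enumerated and averaged, which is
  deterministic and supersedes any sampled subset.  Class prediction uses
  the library's one-vs-one voting rather than Platt probability estimates:
  with three training runs per class, the internal cross-validation that
  probability calibration requires is ill-posed, and for a linear
  multi-class SVM the vote and the calibrated argmax coincide except in
  rare tie cases.  Chance 33.33%.
* **Searchlight** — cubic neighborhoods (default edge 7 → 343 voxels),
  clipped at volume boundaries and intersected with the mask; centers whose
  cube retains fewer than 50% of edge³ in-mask voxels are skipped.  Group
  inference on maps is out of scope here; the engine returns per-center
  statistic volumes.

A structural note on the city classifier: full trial simulations are
city-decodable even with `gamma_city = 0` whenever `rho_shared < 1`,
because per-city store codes *are* environment-specific codes.  Null
calibration of the classifier therefore uses pure-noise run patterns, which
is also what the calibration quantity reported by `scripts/acceptance.py`
computes (1500 replicates; the Monte-Carlo SE of the reported mean is
≈0.4 percentage points).

## Modulation analysis

Partial Spearman correlation: rank-transform all variables, residualize the
ranked x and y on the ranked control(s) plus intercept, Pearson-correlate
the residuals.  The analysis unit is the template–trial pair within subject
(activation = mean signal of the pair's trial in the candidate region;
similarity = the pair's Fisher-z r; control = the target ROI's own
activation) — the only unit that yields per-condition correlations within
subject; a subject-level mode is available by feeding subject means.
Group inference: one-sample t vs 0 per (region, condition) with
Benjamini–Hochberg FDR.  Cohen's d for paired contrasts is mean difference
/ SD of differences.

## Problem sizes and calibration checks

Recovery sweeps use 50 synthetic subjects per condition; the
type-I calibration of the repulsion score uses 20 groups of 27 subjects
(group-level one-sample t, α = 0.05), with the observed rejection count
compared against its binomial band; chance-level calibrations use
1000–1200 noise replicates so the Monte-Carlo SE is well inside the
asserted bounds (±1 percentage point for the city classifier, ±0.02
Fisher-z for the SVR).  These sizes were chosen from the variance of the
statistics (per-replicate SDs of ≈14 percentage points and ≈0.23 z), not
from any observed pass/fail margin.

## Known limitations

* The pattern-level generator bypasses the GLM; the BOLD → LS-S path is
  exercised separately (driver 08) at reduced scale.
* Voxel pooling induces a random, seed-specific linear mixing; voxel-space
  correlations between orthogonal neuron codes are zero only in
  expectation, which adds within-subject (not systematic) variance.
* Searchlight group statistics (cluster correction) are not implemented;
  cohort-scale whole-brain inference is out of scope.
* The interface is the library plus the numbered drivers; no console
  entry point is installed.
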