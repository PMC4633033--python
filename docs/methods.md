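# Methods

This note documents the models and procedures implemented in `bmiconn`, the
choices made where the design was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## Structural networks

A subject's structural connectome is built from fiber records — unordered
region pairs with a length in mm, as produced by a streamline tractography
stage that is outside this package's scope.  Fibers are filtered to the
anatomically plausible 20–500 mm range (bounds inclusive; the conventional
reading of a stated range).  The edge weight between regions *u* and *v* is
the fiber density

```
FD(u, v) = 2 / (S_u + S_v) · Σ_f 1 / l(f)
```

with `S_u`, `S_v` the cortical surface areas of the endpoint regions and
`l(f)` the length of each connecting fiber.  Units are mm⁻³ as implied by the
formula; densities are never rescaled.  The network is undirected (diffusion
tractography cannot distinguish efferent from afferent connections).  Pairs
without a surviving fiber carry density 0 **and** an explicit entry in a
presence mask: downstream subject-exclusion logic must distinguish "no
fiber" from "tiny density", and a zero in the matrix alone cannot.

## Functional networks

ROI time series are cleaned by least-squares nuisance regression (an
intercept is always included; motion/WM/CSF regressors are caller-supplied
columns) and a hard discrete-Fourier band-pass, default 0.009–0.08 Hz.  The
mask filter has no roll-off shaping; an in-band sinusoid keeps its RMS
amplitude to within a fraction of a percent, while the peak can ring by a few
percent (Gibbs) — a deliberate trade for exact, invertible band selection.
Runs are concatenated after per-run demeaning so that run-offset steps do not
masquerade as low-frequency signal.

Edges are Pearson correlations between region time series, stabilised with
the Fisher r-to-z transform (|r| is clamped to 1 − 1e−7 before `atanh`).  A
region's **mean functional connectivity** — a scaled degree centrality — is
the mean of its z values to all other regions.  The average is taken over
*z*, not raw *r* (the matrix is z-transformed before any analysis, and
averaging on the variance-stabilised scale is the standard choice), and it
excludes the diagonal, whose constant 1 would bias every region identically.
Negative correlations are kept with their sign; thresholding them is a known
alternative we deliberately do not apply.

## Edge-wise group comparison

For every region pair carried by at least one subject, the densities of
subjects that have the edge are split into healthy-weight (BMI < 25) and
non-healthy-weight groups.  Subjects lacking the edge are excluded for that
edge only; the edge is **eligible** when the excluded fraction is below 20%
(configurable) and both groups retain at least two subjects.  Presence is a
property of a subject's anatomy, not of its group label, so per-edge subject
sets are held fixed across permutations.

The statistic is the pooled-variance two-sample t (a conventional choice for
permutation testing; the procedure is valid for any statistic).  Family-wise
error is controlled with the single-step max-statistic permutation method:
labels are shuffled once per permutation, globally for all edges; each
edge's |t| is referred to its own permutation distribution (uncorrected p)
and to the distribution of the maximum |t| over all eligible edges
(corrected p).  Both p-values use the add-one estimator
`(1 + #exceed) / (B + 1)`, so the smallest reportable p is `1/(B+1)` and the
corrected p can never fall below the uncorrected one.  Default B = 5000,
two-sided, α = 0.05.  Permuted label splits that leave an edge with fewer
than two subjects per group, or zero pooled variance, score t = 0 — a
conservative convention under the max statistic.  Whole-brain testing is
followed by a reward-system filter (at least one endpoint flagged as
thalamus, insula, putamen or orbitofrontal cortex); a reward-only testing
mode is available by restricting the input networks.

## Cross-modal coupling and feature assembly

Each significant edge's density (over subjects with the edge present) is
correlated with the mean functional connectivity of each endpoint; the edge
is retained when either side couples at p < α (α = 0.05, deliberately **not**
multiplicity-corrected — this screen is a per-edge rule, unlike the FWE-
corrected group test).  Features for the regression are: one structural
feature per retained edge, and one functional feature per *distinct* region
whose own side coupled significantly; a region shared by several retained
edges contributes a single functional feature.  In the design matrix absent
edges contribute density 0 so every subject has a complete row; the coupling
correlations themselves use present subjects only.

## BMI prediction

Features are standardised to unit variance (they mix density and z units),
the response is centred, and PLS1 components are extracted by NIPALS with
X-deflation.  NIPALS components are nested, so a single fit yields the
coefficient vectors of every smaller model; the leave-one-out PRESS curve is
computed with one batched pass over all folds (fold *f* is the standardized
design with row *f* zeroed, which is algebraically identical to deleting the
row).  The LV count is the smallest k at which PRESS stops improving
(`PRESS(k+1) ≥ PRESS(k)`); global-minimum selection is a config option.

Model assessment is leave-one-subject-out CV with the PRESS selection nested
*inside* each training fold — the held-out subject never touches its fold's
standardisation, selection or coefficients.  Reported numbers: RMS error,
percent error `mean(|a − p| / a)·100` (actual BMI in the denominator),
Pearson r between predicted and actual, and an "explained variance" defined
as the training R² of one full-data fit at the modal fold-selected LV count —
a single descriptive number that can coexist with the cross-validated error
estimates.  Per-feature simple regressions (R², F-test p) are computed on the
full cohort.  The modality switch (combined / dti_only / fmri_only) restricts
only the PLSR design matrix; upstream selection is always multimodal.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at the
study's scale: two groups of 60, 116 regions, TR 0.72 s, 1200 time points.

* **BMI**: healthy-weight ~ N(22.53, 1.37²) below 25 kg/m², non-healthy
  ~ N(32.55, 3.60²) at or above 25.  BMI is a linear combination of
  designated features plus Gaussian noise, affinely rescaled per group to
  those distributions and clipped at the boundary, so group labels satisfy
  the 25 kg/m² rule exactly.  The per-group map attenuates the linear R²
  of BMI on the latent score by a constant factor C² ≈ 0.9286 (closed form
  from half-normal moments); `noise_sd_for_signal_fraction` compensates, so a
  requested signal fraction *f* yields population R² ≈ *f* (verified by
  Monte Carlo at n = 2·10⁶).
* **Fibers**: lengths are lognormal truncated to [20, 500] mm with
  ln L ~ TruncNormal(2.90743, 0.35²); the location was solved by quadrature
  so the truncated mean is 26.2 mm, the typical fiber length at this
  resolution.  Counts per anatomically present pair are Poisson (mean 6 by
  default); a fixed fraction of pairs (default 0.6) is never connected.
  A planted edge with effect size *d* shifts the non-healthy group's Poisson
  rate by `d·sqrt(λ_mid)` with λ_mid solving the pooled-SD equation, giving
  an across-subject Cohen's d on fiber density within a few percent of *d*
  (length variability dilutes it slightly).
* **Time series**: every signal is built from unit-variance Gaussian noise
  with spectral support restricted to 0.009–0.08 Hz, so essentially all
  power is in-band by construction.  Regions share one common factor
  (amplitude 1) plus idiosyncratic noise; for a coupling edge, the target
  region's factor amplitude is `1 + 0.35·(α·z + sqrt(1−α²)·ε)` where *z* is
  the subject's standardised edge density.  Mean FC responds to the amplitude
  almost deterministically; the residual attenuation ρ ≈ 0.94 (measured once
  by Monte Carlo at the default scale and frozen) is divided out,
  `α = target_r / 0.94`, so the realised density–mean-FC correlation lands
  near `target_r`.  At substantially smaller time-series lengths the realised
  coupling runs ~10% low, well inside the generator's stated ±0.15 band.
* **Reference configuration** (`default_spec`): ten planted edges (d between
  0.9 and 1.2), each touching a reward region; six of them coupled (one on a
  single side, two sharing a reward region, targets spanning 0.24–0.52); BMI
  driven by three structural and two functional features at signal fraction
  0.57.
* **Feature-level cohorts** (`simulate_feature_cohort`): for regression
  studies that do not need imaging plumbing, features follow a latent-factor
  model (pairwise correlation 0.3) with BMI driven by three structural and
  two functional features.  By default all features share one factor; for
  modality-synergy studies the structural and functional blocks load on
  independent factors (`shared_across_modalities=False`), because synergy is
  only a meaningful question when each modality carries complementary
  signal — with a single shared factor either modality can largely proxy the
  other.
* **Randomness**: one root seed feeds named substreams
  (atlas / skeleton / fibers / timeseries / bmi / features), so stages can be
  regenerated independently and a cohort is bit-identical under a fixed
  spec + seed.

What the generator does **not** emulate: raw diffusion or BOLD volumes, head
motion, physiological noise spectra, spatial autocorrelation of parcels,
hemispheric symmetry, age/sex structure, or realistic between-edge density
covariance.  Tests passing on these cohorts demonstrate the statistical
machinery (calibration, power, selection, cross-validation hygiene), not
performance on real imaging data.

## Numerical choices and problem sizes

* Degenerate inputs raise typed errors: constant feature columns and
  zero-variance regions are named; coupling needs ≥ 4 paired observations;
  the t statistic needs ≥ 2 values per side and nonzero pooled variance.
* Permutations are processed in blocks of 512 to bound memory on large edge
  sets; p-values are exact add-one estimators, never zero.
* File round-trips print floats with 17 significant digits (lossless).
* The statistical test-suite checks run at explicitly chosen sizes — e.g.
  200 null cohorts of 30 + 30 subjects over 21 edges with 500 permutations
  for calibration, 50 replicate cohorts of 120 subjects for power and signal
  recovery, 25 for the modality-synergy comparison — chosen as the smallest
  designs at which the checked effects are comfortably identified.
* The end-to-end determinism check and the worked examples run the full
  file-backed pipeline; the reference analysis in `scripts/acceptance.py`
  uses the full default cohort (120 subjects, 116 regions, 5000
  permutations).

## Known limitations

* The permutation-label universe is the set of subjects appearing in at
  least one eligible edge; with the default 20% exclusion rule this is
  effectively the whole cohort.
* PLS1 only (single response); no support-vector or other learners.
* No cluster/NBS-style corrections, partial correlations, or centralities
  beyond mean FC; no covariate adjustment (the study design assumes matched
  groups).
* The "explained variance" estimator is a training-set quantity at a
  cross-validation-selected complexity; alternatives (cumulative Y-variance
  of the LVs) would give similar but not identical numbers.
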