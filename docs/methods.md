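# Methods

This note documents the models, parameter choices and numerical policies
behind `wheatlai`, and what the synthetic-data experiments do and do not
demonstrate.

## The estimation problem

Leaf area index (LAI, one-sided leaf area per unit ground area,
dimensionless) is a canopy-structure trait that drives light interception
and yield formation in winter wheat. Canopy reflectance between 350 and
1350 nm carries an LAI signal with a characteristic sign structure:
negative correlation in the visible, where leaf pigments absorb and the
(brighter) soil background is progressively occluded as the canopy closes,
and positive correlation in the NIR, where leaf tissue scatters strongly.
The pipeline estimates per-plot LAI from that signal per growth stage
(jointing, booting, flowering, grain filling), using 48-plot stage
datasets.

## Synthetic canopy generator

The field spectra the methodology was developed on are not shareable, so
the package generates stand-in datasets with a *planted, recoverable* LAI
dependence:

- **Leaf optics**: a NIR plateau (default 0.5) minus Gaussian absorption
  troughs — pigments at 450 nm (width 100 nm, depth 0.45) and 670 nm
  (width 50 nm, depth 0.42), leaf water at 970 nm (55 nm, 0.12) and
  1200 nm (70 nm, 0.15). The red edge emerges from the long-wavelength
  shoulder of the 670 nm trough.
- **Soil**: a bright line 0.25 + 5·10⁻⁵·(λ − 350), above the leaf in the
  visible and below it in the NIR, so the soil/leaf crossover sits on the
  red edge (~716–733 nm) and the band–LAI correlation changes sign there.
- **Canopy**: two-flux Beer–Lambert mixing
  `R(λ) = R_leaf + (R_soil − R_leaf)·e^{−k·LAI}`; per-stage LAI drawn
  uniformly from (1,4) jointing, (2,6) booting, (2,7) flowering, (1,5)
  filling; additive Gaussian band noise (default sd 0.01 reflectance).

This is deliberately *not* a radiative-transfer model (no PROSAIL-style
leaf biochemistry, no view/illumination geometry, no multiplicative sensor
effects, no treatment structure). The design goal is testability: a
single-latent monotone LAI→reflectance link whose recovery can be verified
exactly. Two consequences matter:

- **Extinction coefficient k = 0.08.** Field wheat canopies have effective
  extinction coefficients of roughly 0.3–0.7; here k is deliberately at
  the bottom of (below) that range. Because every band of a noise-free
  dataset is affine in the single latent z = e^{−k·LAI}, a *linear* model
  can at best reach R² = corr²(LAI, z), which degrades with the curvature
  of the exponential over the LAI range. At k = 0.08 that ceiling is
  ≥ 0.997 over the widest stage range, so linear-recovery tests are sharp;
  at field-realistic k the ceiling would confound model error with
  generator curvature. The SVR path is insensitive to this choice.
- **Noise-free |ρ| is near 1, not 1.** Pearson correlation of an affine
  function of z with LAI equals corr(z, LAI), which is slightly below 1
  because z is a nonlinear (monotone) transform of LAI; rank correlation
  is exactly ±1. Tests therefore assert |ρ| ≥ 0.99 plus exact
  monotonicity, not |ρ| = 1.

Passing tests show the pipeline recovers a clean planted signal and is
correctly calibrated on null data; they do not show that the methodology
performs comparably on field spectra, whose noise is structured
(row effects, water-vapour bands, bidirectional effects) and whose
LAI–reflectance link is confounded with chlorophyll and canopy geometry.

## Preprocessing

Resampling is linear interpolation onto `arange(350, 1351, 1)` nm
(1001 bands); extrapolation is refused. Savitzky–Golay smoothing defaults
to window 11, order 2 — a common choice for 1 nm canopy spectra; the edge
policy is scipy's `interp` mode (polynomial fitted to the shrinking edge
window), so polynomial spectra of degree ≤ order pass through exactly.

## Fractional differentiation

Grünwald–Letnikov weights are generated by the ratio recursion
c₀ = 1, c_k = c_{k−1}(k−1−α)/k, which is numerically stable and terminates
exactly at integer orders; it equals (−1)^k·binom(α,k) =
Γ(k−α)/(Γ(−α)·k!) (verified against a Γ-function oracle to 1e−10 relative
at k ≤ 500). The band spacing is the 1 nm grid step (no h^α
renormalization), so spectra must be resampled first. Default history is
the full record to the left of each band; a fixed window is available for
speed. Validity flags: order 0 flags nothing; integer order α needs
exactly α left neighbours, so the first α bands are flagged; fractional
orders under a fixed window m flag the first m bands (truncation changes
the operator there), and in full-history mode the ceil(α) leading bands
carrying the heaviest truncated weights are flagged. Flagged bands are
excluded from screening, never imputed.

## Continuous wavelet transform

The scalogram discretizes W(a,b) = ∫f(λ)·a^{−1/2}ψ((λ−b)/a)dλ with
dλ = 1 grid step and the Mexican hat ψ(t) = 2/(√3π^{1/4})(1−t²)e^{−t²/2}.
Scale labels 1–10 map to dyadic values a = 2¹…2¹⁰ grid steps (the common
ladder in CWT spectroscopy). The kernel is truncated at |t| ≤ 8, chosen so
the truncated tail (≈ 8e⁻³² per side) keeps constant inputs below 1e−8
even at a = 2¹⁰. Boundaries use symmetric (reflect) extension; the margin
`ceil(8a)` per side is recorded per scale and flagged coefficients are
excluded from screening. On the 1001-band grid, scales 2⁷–2¹⁰ are margin
everywhere and hence never enter feature selection — large-scale
coefficients on a window this short are boundary artifacts by
construction.

## Screening

Pearson correlation per (order, band) / (scale, band) cell, two-tailed
significance from t = ρ√((n−2)/(1−ρ²)) on n−2 df (no fixed critical-ρ
table, so any n works), counts at the 0.01 level per row, and top-10
selection by |ρ| with a deterministic tie-break (lower wavelength, then
lower order/scale). Zero-variance features are masked, not zeroed. No
multiple-testing correction is applied — with ~1000 bands per row the 1 %
level admits ~10 false positives per row on null data; this mirrors the
screening design the pipeline implements and is why the permutation
control below matters.

Within the modeling pipeline, screening is computed on the modeling
partition only: selecting features on all samples would leak the held-out
plots into the candidate pool, and on permuted-LAI data such leakage
leaves a substantial spurious validation R². The standalone `screen` CLI
subcommand, which mirrors the descriptive per-stage correlation matrices,
uses all samples.

## Modeling and evaluation

Best-subset regression enumerates all 2ⁿ−1 subsets of the 10 candidates
(1023 OLS fits), ranks by adjusted R², and breaks ties toward the smaller
subset then lexicographic order; rank-deficient designs are fitted by
pseudo-inverse and flagged. The subset size is therefore an *outcome*, not
a setting. The SVR is ε-insensitive with RBF kernel on standardized
features; the grid is C ∈ {0.1, 1, 10, 100}, γ ∈ (1/p)·{0.1, 1, 10} with p
the feature count (the `scale` heuristic after standardization), ε ∈
{0.01, 0.1}, chosen by seeded 5-fold CV on the modeling partition. The
75/25 split is a seeded uniform random partition (36/12 at n = 48).

R² is the squared Pearson correlation between measured and estimated
values — on validation data this differs from 1 − RSS/TSS and is the
convention reported here; RMSE is in LAI units; nRMSE = 100·RMSE/mean of
measured, classified as excellent (≤10 %), good (≤20 %), moderate (≤30 %),
poor (>30 %), boundaries inclusive on the left class.

## Determinism and problem sizes

All randomness flows from one root seed through named `SeedSequence`
children (per stage: simulation, split, SVR folds), so a config + seed
reproduces every artifact byte-identically. The shipped experiments use
the study-scale defaults throughout — 48 plots per stage, 1001 bands, 21
differentiation orders, 10 wavelet scales, 20-seed replications for the
statistical checks — which keep a full four-stage run under ~10 s on one
core.

## Known limitations

- One latent variable drives all bands of a synthetic dataset; real
  canopy spectra have band-specific confounders, so feature-selection
  behaviour on real data will differ (the synthetic top-10 clusters in a
  few spectral regions).
- Additive i.i.d. noise only; no multiplicative or spectrally correlated
  sensor model.
- The significance screen is uncorrected for multiplicity by design.
- Large wavelet scales are unusable on a 1000-band window (see above);
  analyses needing them require longer spectra.
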