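# Methods

## The measurement being modelled

A ToF-SIMS imaging run rasters a pulsed primary-ion beam over a tissue
section and records, at every pixel, the counts of secondary ions binned on
an m/z axis. In static mode the detected signal is dominated by counting
statistics, and absolute yields vary with surface condition and dose, so
all quantitative comparison happens on TIC-normalised intensities: the
fraction of a spectrum's total counts carried by each target ion. The
pipeline estimates, per ion and experimental group, that fraction and asks
whether it differs across healthy controls (LEAN), diseased animals (P1)
and treated animals (P2), and by how much treatment moves it back toward
the healthy level.

## Synthetic-study generator

The generator exists so that every downstream stage has a ground truth. It
emulates the study design it is meant to test: 4/8/8 animals across
LEAN/P1/P2, three technical replicate images per animal, 128 × 128 pixels
over a 250 × 250 µm field, negative polarity, m/z range up to 911.

Signal model, per pixel and channel:

```
counts ~ Poisson( f_ion · a_ion,animal · T · s_rep · x(px) )
```

- `f_ion` — the ion's TIC fraction for the group, taken from the bundled
  26-ion reference panel (10 lipid-related and 16 amino-acid-related ions
  with published group means; the panel follows its source verbatim,
  including one amino-acid annotation, m/z 115.011, carried in the lipid
  family).
- `a_ion,animal` — log-normal animal-level scale, mean 1, CV 0.10 by
  default. This makes between-animal variance exceed between-replicate
  variance, so ANOVA on animal-level means is neither trivial nor
  powerless. The value is a stipulation: the source reports SEMs but no
  variance decomposition.
- `T` — expected TIC per pixel. By default derived from an areal ion dose
  (`DEFAULT_TIC_PER_UM2` = 1310.72 counts/µm², i.e. 5000 counts in a 2 µm
  pixel): at the static-SIMS fluence limit of 10¹² primary ions/cm², a
  useful yield × transmission of ~0.13 gives counts of this order. Deriving
  `T` from dose rather than fixing it per pixel means coarsening the raster
  (e.g. 32 × 32 test images) conserves ROI counts, so the counting
  statistics of an ROI do not depend on raster resolution.
- `s_rep` — per-replicate log-normal TIC scale (CV 0.05), emulating
  dose/ionisation drift between acquisitions. Removed exactly by TIC
  normalisation.
- `x(px)` — smooth multiplicative texture field (Gaussian-filtered white
  noise, mean 1, CV 0.15, correlation length 30 µm ≈ sinusoid/lobule
  spacing). Liver microstructure is homogeneous at this scale, so the field
  is smooth, with no sharp compartments. Because it multiplies all channels
  equally it cancels from TIC-normalised ROI means.

A broadband background of 50 pseudo-ions (the five calibration references
plus 45 positions spread over the mass range, weights decaying with mass)
absorbs the TIC fraction not assigned to target ions, making normalisation
non-degenerate. `drift_ppm` optionally mis-scales the m/z axis
multiplicatively to exercise calibration. With `counting_noise=False`,
`tic_cv=0`, `texture_cv=0` and `animal_cv=0` the generator is fully
deterministic and the pipeline must return the panel means to numerical
precision (verified to 1e-12 relative).

What the generator does **not** model: charging, detector dead time, matrix
effects, fragmentation chemistry, peak shape/overlap on a dense axis (the
channel axis is sparse, one channel per ion), or any real spatial
biochemistry. Passing tests therefore demonstrate correctness of the
statistical machinery under a known sampling model — not robustness to
instrumental artefacts.

## Preprocessing

- **Calibration.** Time of flight scales with √(m/z), so a degree-1
  least-squares map is fitted in √(m/z) space from observed reference-peak
  positions (most intense channel within ±0.5 Th of each expected
  reference) to their expected positions and applied to the whole axis.
  Degree 2 is available for larger drifts. Fewer than two detectable
  references ⇒ calibration skipped with a warning flag; any post-fit
  residual above 300 ppm ⇒ validation-failure flag. A 200 ppm injected
  drift is corrected to < 10 ppm residual at all five references.
- **ROI.** Centred square crop, default 150 µm. Side in pixels is
  round-half-up(size/pixel), offset floor((extent − side)/2) — stated so
  results are bit-reproducible (128 px / 250 µm field → 77 px crop at
  offset (25, 25)).
- **Integration.** Sum of counts within ±0.05 Th of each ion (FWHM at
  m/Δm ≈ 4000 is ~0.06 Th at m/z 241; configurable, ppm mode available).
  Neighbouring windows are truncated at the m/z midpoint so no channel is
  counted twice.
- **Normalisation.** Division by the ROI total ion count over *all*
  channels, giving dimensionless fractions that sum to 1 over the spectrum.
- **Aggregation.** Technical replicates are arithmetic-averaged to one row
  per animal before statistics, so inference runs at n = 4/8/8 animals:
  replicates are pseudoreplicates of the same biological sample. A `pool`
  policy keeps replicate rows for sensitivity analyses.

## Statistics

Classical one-way fixed-effects ANOVA (F with k−1, N−k df) with
Tukey–Kramer studentized-range pairwise p-values (valid at unequal n).
Degenerate inputs follow explicit conventions: all observations identical →
F = 0, p = 1 with a warning; zero within-group variance with distinct
means → F = ∞, p = 0 with a flag.

Benjamini–Hochberg step-up adjustment is applied within each ion-class
family by default — the lipid and amino-acid panels are reported as
separate families with separate significance counts — and can be pooled
into one family by configuration.

Fold changes use ratios of group means of animal-level values (not means of
per-animal logs); this convention reproduces the published fold-change
columns from the published means. Trend classification is by sign pattern:
both contrasts (LEAN vs P1, P2 vs P1) positive → Up, both negative → Down,
otherwise Mixed; an exact zero falls to Mixed, the residual
"divergent/bidirectional" category. The recovery index is reported
unclipped, with the denominator declared degenerate below 1e-12 absolute
(result undefined with a flag). It is affine-invariant: any y → a·y + b
(a > 0) applied to all three means leaves it unchanged.

Shapiro–Wilk (per group, n ≥ 3) and Levene (classical, centred on the
mean) are reported as diagnostics only and never switch the analysis to a
nonparametric test.

### Known limitation: trend stability at near-zero effect sizes

Four panel ions have a published |log₂FC| in one contrast below ~0.05
(smallest: 0.0057, a 0.4% mean shift). With the default 10% animal-level
CV, the sampling SD of an estimated log₂ contrast at n = 4–8 animals is
0.05–0.07, so the *sign* of such a contrast — and hence the Up/Down/Mixed
label — is irreducibly unstable for those ions: a direct Monte Carlo on the
group means alone puts the expected panel-wide mislabeling rate at ~11%,
and the full pipeline measures ~11% over 100 simulated studies.
Well-separated ions (min |log₂FC| > 0.1) classify essentially perfectly.
Group-mean estimates themselves are unbiased (< 2% relative bias over 100
studies), and under label permutation the per-family fraction of q < 0.05
calls stays below 0.05 — the instability is a property of sign
classification near zero effect, not of the estimator or the FDR control.

### Class contributions

Per sample, amino% = 100 · Σ(amino-class intensities) / Σ(amino + lipid
intensities), lipid% its complement; `other`-class ions are excluded.
On the bundled 26-ion panel these percentages describe that panel only —
a full-spectrum ion list (hundreds of peaks) would be needed to reproduce
tissue-level class balances, so the panel values are not comparable to
whole-spectrum figures.

## Reporting

Volcano tables use the Tukey pairwise p for the plotted contrast (a
per-contrast volcano needs a per-contrast p, not the omnibus ANOVA p;
configurable) with strict thresholds |log₂FC| > 0.6 and p < 0.05.
Clustering standardises each ion to Z-scores across samples and uses Ward
linkage on Euclidean distances — the choice is the package's own, made
deterministic through scipy's index-ordered tie-breaking; zero-variance
ions are dropped with a warning. The heatmap takes the top-k ions by
ascending q (default 40). Boxplots follow the Tukey convention (whiskers at
the last points within 1.5 × IQR). Ion maps divide per-pixel integrated
counts by per-pixel TIC and share one fixed colour range per ion across
groups so group images are comparable. Every figure's underlying numbers
are exported as CSV and regenerate bit-identically from the same inputs.

## Problem sizes used in the test suite

Simulation-backed tests run on scaled-down rasters — 32 × 32 pixels (ROI
19 × 19) with the dose-derived TIC budget, or smaller for unit tests — and
reduced animal counts where group structure is irrelevant. The dose-derived
budget makes these rasters statistically equivalent per-ROI to full-size
images, and the noise-free closure test is exact at any size. The
repeated-study checks use 100 seeds; the permutation-null check 200
permutations.
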