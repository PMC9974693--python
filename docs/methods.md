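# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Aroma-value scoring

The aroma value AV = c/t (concentration over taste threshold, both in
µg/L) is linear in concentration and assumes additivity of aroma
contributions — a deliberate simplification: perceptual interactions
(masking, synergy) are ignored, as is the concentration dependence of
odour character. Units: mash density is taken as 1 kg/L, so µg/kg and
µg/L are interchangeable and mg units convert by 1000. Compounds with
no published threshold are *unscorable*: they are excluded and listed
on the result object, never silently scored 0. The internal-standard
compound (2-heptanone by default) is excluded via the `exclude`
argument of `compute_aroma_values`.

Selection keeps compounds whose maximum aroma value over samples
**reaches or exceeds** 10 (boundary inclusive). Reported aroma-value
ranges round to the nearest integer with halves away from zero.

The bundled reference tables include the published mash concentration
ranges and thresholds. A handful of the published aroma-value ranges
are not consistent with their own concentration/threshold inputs (e.g.
a "hexenal 10–51" range against hexanal inputs implying ≈541–2919, and
an ethyl 3-methylbutanoate "0–37" against inputs implying 10–110); the
package always reports the computed values and makes no attempt to
reproduce those rows. One parsing ambiguity in the source table
(2-pentanone: range 2.4–3.88 µg/kg with threshold 60,000 µg/L vs
2.4–3.8 with 860,000) is resolved to the former; both readings leave
the compound far below the selection cutoff.

## Attribute grouping

The four attributes (fruity, green/vegetative, floral, microbiological)
come from the wine aroma wheel. Grouping is operationalized as:

1. PCA of the autoscaled (z-scored, n−1 SD) concentration matrix.
   Autoscaling is the natural choice when variables span µg/L to mg/L;
   it also makes the loadings identical whether computed from
   concentrations or from aroma values (which differ only by per-column
   scale factors). Eigenvector signs are fixed by making each
   component's largest-magnitude coefficient positive.
2. Nearest-centroid assignment in PC1/PC2, with centroids from seed
   compounds of known attribute. Seed compounds keep their seed
   attribute; the centroid rule classifies only unseeded compounds.
   This matters: with centroids built from the full published
   membership, pure nearest-centroid would re-assign ethyl
   3-methylbutanoate (fruity) to green/vegetative and 1-hexanol to
   fruity — the historical grouping was partly judgment-based, and the
   seed semantics preserve it exactly while still giving a
   deterministic geometric rule for new compounds.
3. Descriptor overrides win over everything (1-hexanol →
   green/vegetative by default, following its "leaf alcohol" / green
   descriptors). Exact centroid ties break by attribute enumeration
   order (fruity < green_vegetative < floral < microbiological).

Attribute scores are plain sums of aroma values over assigned
compounds; attributes with no compound present score 0. Summation is
conservative (the four scores add up to the total assigned aroma value)
and additive over disjoint compound sets.

## Spectral preprocessing

Spectra live on the fixed 400–1700 nm, 5 nm grid (261 channels); all
operations are grid-preserving. The visible range is retained (the
sensor carries both Si and InGaAs detectors); no log(1/R) conversion is
applied by default (a config flag exists).

- **SNV** z-scores each spectrum (n−1 SD); undefined for constant
  spectra (rejected).
- **MSC** fits x ≈ a + b·ref by least squares and returns (x−a)/b. The
  reference is always the *training-set* mean, never a statistic that
  includes test samples — this is what makes the cross-validation
  leak-free. Fits with |b| < 1e-10 are rejected as degenerate.
- **First derivative**: Savitzky–Golay, window 5, polynomial order 2
  (configurable), units value·nm⁻¹, edges handled by the edge
  polynomial fit. Exact on quadratics; chosen because it is the
  standard in vendor NIR software and noise-robust. The combined
  pipeline order is scatter correction first, then derivative, matching
  the convention that the derivative applies to the pretreated spectra.

## PLS calibration and model selection

NIPALS PLS for a univariate response, mean-centered X and y, deflation
of X only (equivalent to y-deflation for univariate y). Components stop
early (with a warning) when the rank is exhausted. Predictions use
β = W(PᵀW)⁻¹q; at full rank this equals the minimum-norm OLS solution.
Mean-centering only — no autoscaling of channels — is the default.

Segmented cross-validation partitions samples into S = 5 contiguous
blocks in input order, sizes differing by at most one (36 samples →
8,7,7,7,7). Within each fold the pretreatment statistics *and* the PLS
model are refit on the training folds only, so a sample's own CV
prediction is independent of its reference value (tested by
perturbation). A seedable shuffled-fold option exists for robustness
checks.

Model selection evaluates {none, SNV, MSC} × {1..15} LVs — the first
derivative is applied in every cell — and picks the global SECV
minimum; exact ties go to the smaller LV count, then to pretreatment
order none < snv < msc. Metric conventions: R² as squared Pearson
correlation (a 1 − SSE/SST variant is selectable), SEC with denominator
n − 1 − LV, SECV with denominator n, RPD = SD(y, n−1)/SECV (infinite
sentinel when SECV = 0). These denominators follow common chemometrics
convention; the vendor software's exact formulas are undocumented.

## Synthetic data generator

The generator emulates the study conditions, not real grape-mash
physics:

- **Concentrations**: log-normal marginals with the published
  per-compound arithmetic means and SDs (log-normality because
  concentrations are positive and right-skewed, with several published
  SDs exceeding their means). Compounds sharing an attribute share a
  standard-normal latent factor with loading √ρ, ρ = 0.6 by default,
  inducing within-attribute correlation on the log scale. One published
  inconsistency is inherited knowingly: the linalool average (2.3 µg/L)
  is below its published minimum (3.5 µg/L); the generator uses the
  average/SD as printed.
- **Spectra**: clean spectrum = Σ concentration × Gaussian band +
  fixed background (broad water/sugar-like bands plus a gentle slope).
  The band library is fictional but fixed (shipped as
  `data/synthetic_band_library.csv`); per-compound amplitudes are
  1/mean-concentration so every constituent band varies on an O(1)
  scale. Observed = a + b·clean + ε with a ~ N(0, 0.01),
  log b ~ N(0, 0.005), ε ~ N(0, 0.002) per channel by default. At these
  defaults the measured per-band signal-to-noise ratio (SD of the clean
  band signal across samples over the RMS distortion at the band
  center) is ≥ 28 at n = 200, i.e. the generator operates in the
  SNR ≥ 20 regime that the parameter-recovery guarantee refers to.
- **Panel scores**: latent intensity = standardized attribute score ×
  effect scale + panelist random effect (SD 0.3) + noise (SD 0.5),
  cut at (−0.5, 0.5, 1.5) into the 1–4 scale. 30 panelists by default.

Defaults: 36 samples (the study's calibration size). Everything is
driven by one integer seed through spawned child generators, so output
is bit-reproducible and the three stages are independently stable.

**What passing tests show — and don't.** On this generator the full
pipeline (generate → score → group → calibrate) recovers every
attribute with R²CV ≥ 0.95 at n = 200, and under strong scatter
(offset/log-gain SD 0.3) a scatter-correcting pretreatment wins SECV
selection in ≥ 90% of replicates for the green/vegetative attribute.
Two honest caveats. First, the spectra are exactly linear in the
concentrations, so recovery demonstrates correctness of the chain, not
real-world feasibility: real mash spectra contain nonlinear matrix
effects, temperature drift and particle-size variation the generator
does not model. Second, the pretreatment-win property is a statement
about attributes whose reference score has a high mean-to-SD ratio
(there the multiplicative gain error is the binding error source);
for fruity/floral — dominated by heavy-tailed trace esters, score SD
comparable to its mean — the uncorrected model already sits at its
accuracy ceiling and the pretreatment choice is close to a coin flip.

## Sensory statistics

Scores are treated as numeric, as is conventional for RATA intensity
data; with 4 ordinal levels and ~30 raters per cell the F-test is
robust in level (verified by a type-I calibration test: ≈5% rejections
over 200 null seeds), but an ordinal model would be more efficient for
strongly skewed cells. Zero within-group variance with non-zero
between-group variance yields an infinite F and a p = 0 sentinel with a
flag. The sensory PCA runs on the panelist-level observation matrix
(panelist × solution rows), centered and not autoscaled (all columns
share the 1–4 scale); autoscaling and a Bonferroni/Holm correction
across attributes are available as flags but off by default. Whether to
run the PCA on panelist-level or solution-mean observations was an open
choice; panelist-level is the default because it preserves the
between-rater spread that dominates such panels.

## Problem sizes

Default test and reproduction sizes: n = 200 for parameter recovery,
20 replicates of n = 60 for the pretreatment-win rate, 200 seeds for
the ANOVA type-I calibration, n = 10,000 for generator moment checks —
sizes at which the Monte-Carlo bands in the tests are comfortably
narrow on a single CPU.

## Known limitations

- The aroma-value reference is a simplified proxy for perceived aroma;
  additivity and threshold accuracy are assumptions.
- The grouping rule reproduces the historical assignment by
  construction (seeds); its nearest-centroid extension to new compounds
  is this package's operationalization, not an established standard.
- Published calibration figures for the real 36-sample dataset cannot
  be reproduced because those spectra are not public; calibration
  correctness is established by oracle equivalences (OLS at full rank,
  closed-form regression, exactness on polynomials) and synthetic
  recovery instead.
- The segmented (contiguous-block) CV mirrors vendor behaviour; with
  samples ordered by acquisition time it can under- or over-estimate
  error relative to random folds, which are available via
  `shuffle=True`.
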