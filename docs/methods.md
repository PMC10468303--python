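# Methods

This note documents the models and numerical choices behind `flyeye`, the
defaults that matter, what the synthetic data do and do not emulate, and the
known limitations.

## Image model and quantification

### Preprocessing and ROI

Input micrographs (grayscale or RGB; RGB collapsed with BT.709 luminance
weights) are rescaled to [0, 1] and passed through a **white top-hat**
transform with a disk structuring element. The top-hat (image minus its
opening) removes any background structure wider than the element and keeps
bright blobs smaller than it, so the facet reflections survive while
illumination gradients vanish. The structuring radius should be ≈ 1.5× the
expected ommatidium radius (default 10 px; the synthetic fixtures use 7 px
for 4 px dots). A flat image maps exactly to zero.

ROI selection then proceeds in three steps:

1. **Bright-pixel detection** — Otsu's threshold on the top-hat image by
   default; a fixed intensity quantile is available as an alternative rule.
   A flat image yields an empty set with a warning.
2. **Centroid-distance pruning** — Euclidean distances from every bright
   pixel to the bright-pixel centroid are computed and pixels beyond the
   0.8 empirical quantile are discarded. The quantile interpolates linearly
   between order statistics and ties are kept on the retain side
   (distance ≤ quantile survives), so the retained fraction is within 1/n
   of 0.8 for distinct distances. This trims out-of-focus periphery: the
   eye is a 3-D organ and only the central facets sit in the focal plane.
3. **Confidence ellipse** — mean and covariance of the surviving pixel
   coordinates define an ellipse whose semi-axes are the covariance
   eigenvalue square roots scaled by the chi-square(2) quantile at the
   confidence level (default 0.95). Collinear pixel sets raise a
   rank-deficiency error. Masking outside the ellipse is idempotent and the
   fit is translation-equivariant.

### Segmentation and per-ommatidium geometry

Within the ROI, foreground is an Otsu threshold computed **on ROI pixels
only** (the masked-out background would otherwise bias it), and ommatidia
are 8-connected components of at least `min_cluster_size` pixels (default
5, rejecting noise specks). Clusters touching the ROI boundary are retained
by default (`exclude_boundary` flips this; whether the original analyses
excluded them is not stated anywhere we know of).

Per cluster:

- **area** — pixel count;
- **perimeter** — chain-code border estimator (orthogonal steps weight 1,
  diagonal steps √2, with corner correction), as implemented by
  scikit-image `regionprops`. Like all discrete perimeter estimators it
  under-measures very small blobs; the bias fades with blob size, which is
  why the scale-equivariance test holds perimeter to a coarser tolerance
  than the other length metrics;
- **radii** — distances from the centroid to boundary pixels (cluster
  pixels with a 4-neighbour outside the cluster) **plus 0.5 px**: boundary
  pixel centers sit about half a pixel inside the true edge, and without
  the correction radii carry a constant −0.5 px bias that breaks scale
  equivariance at small radii. Summarized as mean/min/max/sample SD;
- **eccentricity** — from second central moments, `sqrt(1 − λ₂/λ₁)`; 0 for
  a circle.

Nearest-neighbour distances between cluster centroids are exact
(KD-tree, verified against the all-pairs scan). The 16 image metrics are
the arithmetic mean and sample SD (n−1 denominator throughout) of the eight
underlying measurements; they require at least two ommatidia.

The trait taxonomy used for presentation labels five retained metrics
*central* (nn mean, ecc mean, area mean, radius_mean mean, perimeter mean)
and nine *dispersion* (nn SD, area SD, radius_mean SD, perimeter SD,
radius_min SD, radius_max mean, radius_max SD, radius_SD mean,
radius_SD SD); retained metrics outside the fixed taxonomy (ecc SD,
radius_min mean) are flagged for review rather than silently classified.

## Synthetic eye images

The generator renders anti-aliased disks (linear half-pixel edge ramp,
max-compositing) at hexagonal lattice sites — row pitch `spacing·√3/2`,
odd rows offset half a spacing — so every interior site has six neighbours
at exactly `spacing`. Degeneration operators:

- **fusion** — adjacent pairs are sampled as a *matching* (each ommatidium
  fuses at most once), each accepted with probability `fusion_rate`, and a
  bright capsule of radius 0.6× dot radius bridges the pair. Because fused
  pairs never chain, the connected-component count is exactly
  `n − #fused_pairs`, which the flood-fill oracle tests exploit;
- **pitting** — with probability `pit_rate` per ommatidium, a dark disk of
  0.45× dot radius at a random interior offset pulls intensity back to
  background, reducing bright area and minimal radius;
- **jitter** — centroids are perturbed by N(0, jitter_sd²) per coordinate;
  positions that leave the frame are clipped and flagged.

Optional additive Gaussian pixel noise is off by default: the acquisition
noise of real stereomicroscope images is unknown to us, so it is exposed as
a free parameter rather than pretending to a calibration. The fixtures
emulate facet geometry only — no pigment or colour, no 3-D curvature, no
specular highlights, no depth-of-field falloff. Passing tests on these
fixtures therefore demonstrates the pipeline's geometric correctness, not
robustness to real-world imaging artifacts.

## Line mixed model, BLUPs and H²

Per trait the model is `Y_ijk = μ + G_i + B_j + L_k + ε_ijk` with fixed
group/batch and random line effects, fitted by REML. The implementation
profiles the fixed effects and residual variance out of the restricted
likelihood and optimizes the single variance ratio λ = σ²_line/σ²_res by
bounded scalar search on log λ (tolerance 1e-8); for one random intercept
`(I + λZZ')⁻¹` has a closed form through per-line sums, making a fit on
100 lines × 10 replicates ≈ 5 ms. Negative variance solutions truncate at
the λ = 0 boundary. The fit agrees with statsmodels `MixedLM` (REML) to
four decimals and with the one-way ANOVA moment estimator to 1e-6 on
balanced data; BLUPs equal the closed-form shrinkage
`w·(line mean − grand mean)`, `w = σ²_line/(σ²_line + σ²_res/r)` on
balanced designs and sum to zero. A reduced model without the fixed terms
(`include_fixed=False`) supports designs measured in a single group/batch.

`H² = σ²_line/(σ²_line + σ²_res)`: group and batch are fixed effects and
contribute no variance to the denominator. The 95% CI is a **parametric
bootstrap** (simulate from the fitted model, refit, percentile interval),
defaulting to 1,000 draws; the speed of the REML fitter is what makes the
recovery experiment (200 panels × 200 bootstrap draws each) affordable in
about 90 s. At true H² = 0.25 (100 lines × 10 reps) the mean estimate is
within 0.01 and CI coverage ≈ 92%.

Validation against human 0–4 severity scores uses Spearman correlation with
average ranks for ties and the analytic large-sample two-sided P (a
permutation P would also be defensible; the analytic one is used and
documented). Trait retention requires H² > 0.05 **and** correlation
P < 0.05. Transgene effects use a two-way fixed-effect OLS with
interaction, reported against the double-negative control cell.

## Association scan

Genotypes are 0/1 homozygote-class calls (inbred lines; a 0/1/2 dosage
would be degenerate). Filters: missing rate > 0.2 or MAF < 0.05 (computed
over non-missing calls). Missing data are handled differently by stage, on
purpose: **mean-imputation** for the PCA (structure estimation wants all
lines) and **case-wise deletion** for each variant's regression (no
imputed genotype–phenotype pairs enter a test). Variants with `n_used ≤ n_covariates+2`
are flagged untested.

PCA standardizes variants to zero mean and unit variance. The number of
retained PCs comes from a sequential **Tracy–Widom test**: for the leading
remaining eigenvalue, the spectrum's effective marker dimension is
estimated by moment matching, `n_eff = m·S1²/(m·S2 − S1²)` (m = number of
eigenvalues, S1/S2 the spectrum's first two power sums) — the
moment-consistent form; common finite-sample variants of this estimator
are badly biased when markers ≈ lines², which is exactly the inbred-panel
regime — the spectrum is rescaled to white-Wishart trace, centered and
scaled per Johnstone (μ = (√(m−1)+√n_eff)², σ = (√(m−1)+√n_eff)
(1/√(m−1)+1/√n_eff)^{1/3}), and compared with tabulated TW1 critical
values (α = 0.05 → 0.9793; log-interpolated between table points;
α ≥ 1 retains everything). Testing stops at the first non-significant
eigenvalue. On white-noise panels across four size regimes the statistic's
upper tail mass at the 0.05 critical value is 2–4%, and ≥ 90% of null
panels retain zero PCs.

Per-variant association is exact OLS of the trait BLUPs on the call plus
covariates, with the two-sided t test on the genotype coefficient.
Complete variants run through a vectorized Frisch–Waugh residualization
(identical, to 1e-10, to the per-variant normal-equations solve used for
variants with missing calls). BH adjustment is applied **within trait** by
default (per-trait reporting convention); a global flag pools all traits
instead — the right choice is genuinely ambiguous and left to the caller.
Hits: significant = adjusted P < 0.05, suggestive = raw P < 1e-5; the two
sets are defined independently. Gene mapping assigns every overlapping
annotation interval (1-based inclusive, ± window); the primary gene of a
multi-gene locus is the smallest start coordinate, ties broken
lexicographically — a deterministic stand-in for upstream pipelines whose
"gene 1" ordering is not reproducible.

## Permutation enrichment

`count_ad_orthologs` counts either **pairs** or **distinct human genes**
(ortholog relations are many-to-many, so the two differ); the mode is a
required explicit choice rather than a default hiding the ambiguity. The
null draws `n_iter` same-size gene sets without replacement from the
universe (all annotated fly genes, not only those with orthologs). For the
pairs mode the count is additive over fly genes, so per-gene weights are
precomputed and each iteration is a weighted sample sum. The P value uses
the add-one rule `P = (1 + #{ho_perm ≥ ho_obs}) / (1 + n_iter)` — the
valid (never anti-conservative) estimator — with the plain proportion
available behind `add_one=False`. Under a null query the P values are
approximately uniform (discreteness of small counts makes the test mildly
conservative below nominal 0.05).

## End-to-end integration design

`run_full` links genotype to phenotype through a per-line **liability**:
the planted causal variant's additive effect plus line-level Gaussian
noise (SD 0.5). Replicate phenotypes add group/batch offsets and
replicate noise (SD 1.0, 6 replicates/line), the mixed model produces
BLUPs, and the scan runs on them. A small image stage (default 6 lines ×
2 replicates) renders eyes whose fusion/pitting/jitter scale with the
line's liability percentile and pushes them through the full quantification
pipeline — it exercises the image path on every run but is not the GWAS
phenotype source, because image-derived noise would only blur the planted
signal the integration test is designed to detect. In the recovery
experiment (162 lines × 5,000 variants, causal variant at MAF ≈ 0.3 with a
1-SD effect, 2 subpopulations at modest divergence, 5% missingness) the
causal variant is the top hit in 20/20 seeded runs.

Problem sizes in the test suite and acceptance script (200 heritability
panels, 200 bootstrap draws, 2,000-variant null scans, 12,000 null tests,
200 null enrichment runs at 2,000 iterations, 20-seed image experiments)
are the package's own choices: large enough that the binomial/KS bands in
the assertions are meaningful, small enough to run on a laptop core in a
few minutes.

## Known limitations

- The image model is 2-D and binary-contrast; pigment loss, glare and
  necrotic patches in real micrographs are not modeled, and segmentation
  quality on real data will depend on the top-hat radius and threshold
  rule, both exposed as configuration.
- The perimeter estimator's small-blob bias means absolute perimeter values
  (unlike their between-group differences) should not be compared across
  image resolutions.
- The mixed model supports a single random intercept (line); designs with
  random batch effects or line×age interactions need a general mixed-model
  package.
- The association model is OLS with PC covariates — no kinship matrix, no
  LD pruning, no inversion modeling beyond what PCs capture.
- Tracy–Widom critical values are tabulated for TW1 at eight α points and
  interpolated between them; exotic α values outside [0.001, 0.5] clamp to
  the table ends (α ≥ 1 retains all tested PCs).
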