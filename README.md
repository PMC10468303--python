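# flyeye

Automated quantification of ommatidial degeneration in the *Drosophila*
compound eye, with the downstream statistics needed to run a forward genetic
screen over an inbred line panel: mixed-model line effects (BLUPs) and
broad-sense heritability, a covariate-adjusted genome-wide association scan
with FDR-based hit classification, and a permutation test for enrichment of
disease-associated human orthologs.

## Who this is for

Fly labs using the rough-eye phenotype as a degeneration readout (e.g. in
neurodegeneration models driven in the eye), and quantitative geneticists
mapping natural modifiers of that phenotype across inbred panels such as the
DGRP. A healthy compound eye is a hexagonal array in which every interior
ommatidium sits a uniform distance from six equidistant neighbours;
degeneration shows up as pitting, fusion and irregular spacing. Manual 0-4
severity scoring saturates quickly; this package instead measures the
geometry of every detected ommatidium and summarizes each image with 16
quantitative traits.

## What it computes

**Image pipeline.** Each micrograph is converted to grayscale and passed
through a white top-hat transform (image minus its morphological opening),
which removes illumination structure while preserving the bright facet
reflections. Bright pixels are detected (Otsu threshold by default), pixels
farther from the bright-pixel centroid than the 0.8 distance quantile are
discarded, and a confidence ellipse (default 95%, chi-square(2) scaling of
the pixel covariance) on the remaining pixels becomes the region of
interest. Inside the ROI, ommatidia are segmented as 8-connected bright
clusters; each yields centroid, area `A`, perimeter `P`, boundary-radius
summaries (mean, min, max, SD) and moment eccentricity
`e = sqrt(1 - λ₂/λ₁)`. The image-level traits are the mean and sample SD,
across ommatidia, of: nearest-neighbour distance, eccentricity, area,
perimeter, radius_mean, radius_SD, radius_min and radius_max — 16 metrics.

**Line statistics.** Replicated per-line trait values follow the mixed model

    Y_ijk = μ + G_i + B_j + L_k + ε_ijk,   L_k ~ N(0, σ²_line),  ε ~ N(0, σ²_res)

with image group `G` and batch `B` fixed and line `L` random, fitted by
REML. Line BLUPs are the conditional modes of `L_k`; broad-sense
heritability is `H² = σ²_line / (σ²_line + σ²_res)` with a parametric
bootstrap 95% CI. Traits are retained for mapping when `H² > 0.05` and
their BLUPs correlate significantly (Spearman) with human severity scores.

**Association scan.** Homozygous inbred genotypes are coded 0/1 (no
heterozygotes exist), variants with missing rate > 0.2 or MAF < 0.05 are
discarded, population-structure covariates are the leading principal
components retained by a Tracy–Widom test on the eigenvalue spectrum, and
each variant is tested by OLS of the trait BLUPs on the minor-class
indicator plus covariates. Raw P values are Benjamini–Hochberg adjusted per
trait; hits are *significant* (adjusted P < 0.05) or *suggestive*
(raw P < 1e-5), and variants map to overlapping genes from an annotation
table.

**Ortholog enrichment.** Given the fly genes mapped by suggestive variants,
count fly–human ortholog pairs (confidence score ≥ 3) whose human partner is
in a disease-association catalog, and compare with random same-size gene
sets: `P = (1 + #{ho_perm ≥ ho_obs}) / (1 + n_iter)`.

All study inputs have synthetic generators with known ground truth
(`flyeye.simulate`): hexagonal lattice images with parametric
fusion/pitting/jitter, replicated phenotypes with chosen variance
components, structured genotype panels with planted causal variants, and
ortholog/catalog tables with a planted overlap.

## Worked example

```python
from flyeye import (LatticeSpec, DegenerationSpec, generate_eye_image,
                    quantify_image, QuantifyConfig)

lat = LatticeSpec(n_rows=8, n_cols=8, spacing=13.0, dot_radius=4.0)
cfg = QuantifyConfig(structuring_radius=7)
healthy, _ = generate_eye_image(lat, DegenerationSpec(seed=0))
rough, _ = generate_eye_image(
    lat, DegenerationSpec(fusion_rate=0.4, pit_rate=0.5, jitter_sd=1.0, seed=0))
for name, img in [("healthy", healthy), ("rough", rough)]:
    m = quantify_image(img, cfg)
    print(name, m.n_ommatidia, round(m.nn_sd, 2), round(m.area_mean, 1),
          round(m.radiusmin_mean, 2))
```

prints

```
healthy 62 0.03 51.2 3.58
rough   45 1.66 74.4 2.38
```

— fusion and jitter raise mean area (51.2 → 74.4 px²) and
nearest-neighbour dispersion (0.03 → 1.66 px) while pitting lowers the mean
minimal radius (3.58 → 2.38 px), the directions that separate degenerate
from wild-type eyes. Downstream:

```python
from flyeye import LineBLUPModel
from flyeye.simulate import PhenoSimSpec, simulate_line_phenotypes

sim = simulate_line_phenotypes(PhenoSimSpec(
    n_lines=100, reps_per_line=10, var_line=1.0, var_residual=3.0, seed=1))
m = LineBLUPModel(include_fixed=False).fit(sim.data)
est = m.heritability(n_boot=1000, seed=2)
print(round(m.h2_, 3), round(est.ci_low, 3), round(est.ci_high, 3))
```

prints `0.183 0.117 0.248`: with a true `H² = 1/(1+3) = 0.25`, this seed's
estimate is 0.183 with 95% CI [0.117, 0.248] — a reminder that individual
panels of 100 lines carry real sampling noise (across 200 such panels the
mean estimate is within 0.01 of 0.25 and CI coverage is ≈ 92%; see the
acceptance report).

The command line mirrors the library:

```bash
flyeye simulate eye --seed 3 --out eye.png
flyeye quantify imgdir/ --metadata meta.tsv --out metrics.tsv
flyeye traits --metrics metrics.tsv --trait area_mean --out-prefix area
flyeye gwas --blups blups.tsv --geno geno.tsv --out-prefix scan
flyeye enrich --query genes.txt --universe universe.txt \
    --pairs diopt.tsv --catalog ad.tsv --iters 1000000 --seed 1 --out enr.json
flyeye run-all --seed 7 --out results/
```

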