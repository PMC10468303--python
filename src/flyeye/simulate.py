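"""Synthetic fixtures with known ground truth.

This module generates every input the analysis pipeline consumes, in place of
the study data it emulates:

* hexagonal ommatidial-array images with parametric degeneration (fusion of
  adjacent ommatidia, pitting, positional jitter),
* replicated per-line phenotypes drawn from the mixed model the trait
  statistics fit (fixed group/batch offsets, random line effects),
* homozygous 0/1 genotype matrices for inbred line panels, with missingness,
  Balding-Nichols-like subpopulation structure and planted causal variants,
* toy fly-human ortholog tables and disease-gene catalogs with a known
  planted overlap.

All randomness flows through one explicit seed per spec; no global RNG state.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LatticeSpec",
    "DegenerationSpec",
    "SyntheticGroundTruth",
    "PhenoSimSpec",
    "GenoSimSpec",
    "SimulatedPhenotypes",
    "generate_eye_image",
    "hex_lattice_centroids",
    "simulate_line_phenotypes",
    "simulate_genotypes",
    "phenotype_from_genotypes",
    "make_ortholog_fixture",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of an undisturbed hexagonal ommatidial array.

    ``spacing`` is the center-to-center distance between nearest neighbours
    (pixels); on a hexagonal lattice every interior ommatidium has six
    neighbours at exactly this distance.  ``image_size`` is (height, width);
    if omitted it is computed so all dots fit with a one-spacing margin.
    """

    n_rows: int = 5
    n_cols: int = 5
    spacing: float = 14.0
    dot_radius: float = 4.0
    image_size: tuple[int, int] | None = None
    background_level: float = 0.08
    dot_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.dot_radius < 1:
            raise ValueError("dot_radius must be >= 1 pixel")
        if not (0.0 <= self.background_level < self.dot_level <= 1.0):
            raise ValueError("require 0 <= background_level < dot_level <= 1")

    @property
    def shape(self) -> tuple[int, int]:
        if self.image_size is not None:
            return tuple(int(v) for v in self.image_size)
        margin = self.spacing + self.dot_radius
        h = math.ceil((self.n_rows - 1) * self.spacing * math.sqrt(3) / 2 + 2 * margin)
        w = math.ceil((self.n_cols - 1) * self.spacing + self.spacing / 2 + 2 * margin)
        return (h, w)


@dataclass(frozen=True)
class DegenerationSpec:
    """Parametric degeneration applied to a lattice.

    ``fusion_rate`` is the probability that an adjacent pair fuses (pairs are
    drawn as a matching, so each ommatidium joins at most one fusion and the
    connected-component count drops by exactly the number of fused pairs).
    ``pit_rate`` is the per-ommatidium probability of a dark pit carved out of
    the dot.  ``jitter_sd`` perturbs each centroid by N(0, jitter_sd^2) in
    both coordinates.  ``noise_sd`` adds optional Gaussian pixel noise; the
    acquisition noise of the emulated micrographs is unknown, so this is a
    free parameter defaulting to zero.
    """

    fusion_rate: float = 0.0
    pit_rate: float = 0.0
    jitter_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fusion_rate <= 1.0 and 0.0 <= self.pit_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter_sd and noise_sd must be >= 0")


@dataclass
class SyntheticGroundTruth:
    """Ground truth for one generated image."""

    true_centroids: np.ndarray  # (n, 2) subpixel (row, col)
    true_count: int
    fused_pairs: list[tuple[int, int]]
    pitted_indices: list[int]
    clipped: bool = False  # any centroid clipped back into bounds after jitter

    def __post_init__(self) -> None:
        self.true_centroids = np.asarray(self.true_centroids, dtype=float)
        assert self.true_count == len(self.true_centroids)
        for i, j in self.fused_pairs:
            assert 0 <= i < self.true_count and 0 <= j < self.true_count
        for i in self.pitted_indices:
            assert 0 <= i < self.true_count


def hex_lattice_centroids(lattice: LatticeSpec) -> np.ndarray:
    """(row, col) centers of an n_rows x n_cols hexagonal lattice."""
    h, w = lattice.shape
    row_pitch = lattice.spacing * math.sqrt(3) / 2
    span_r = (lattice.n_rows - 1) * row_pitch
    span_c = (lattice.n_cols - 1) * lattice.spacing + lattice.spacing / 2
    r0 = (h - span_r) / 2
    c0 = (w - span_c) / 2
    pts = []
    for r in range(lattice.n_rows):
        off = (r % 2) * lattice.spacing / 2
        for c in range(lattice.n_cols):
            pts.append((r0 + r * row_pitch, c0 + c * lattice.spacing + off))
    return np.array(pts, dtype=float)


def _add_disk(img: np.ndarray, center: np.ndarray, radius: float, level: float,
              background: float) -> None:
    # anti-aliased coverage: alpha ramps linearly across the half-pixel edge band
    h, w = img.shape
    r0 = max(0, int(center[0] - radius - 2))
    r1 = min(h, int(center[0] + radius + 3))
    c0 = max(0, int(center[1] - radius - 2))
    c1 = min(w, int(center[1] + radius + 3))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - center[0], cc - center[1])
    alpha = np.clip(radius + 0.5 - d, 0.0, 1.0)
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, background + alpha * (level - background), out=patch)


def _add_capsule(img: np.ndarray, p: np.ndarray, q: np.ndarray, radius: float,
                 level: float, background: float) -> None:
    # bright bridge between two dot centers (distance-to-segment capsule)
    h, w = img.shape
    lo = np.minimum(p, q) - radius - 2
    hi = np.maximum(p, q) + radius + 3
    r0, c0 = max(0, int(lo[0])), max(0, int(lo[1]))
    r1, c1 = min(h, int(hi[0])), min(w, int(hi[1]))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    v = q - p
    vv = float(v @ v)
    if vv == 0:
        return
    t = np.clip(((rr - p[0]) * v[0] + (cc - p[1]) * v[1]) / vv, 0.0, 1.0)
    d = np.hypot(rr - (p[0] + t * v[0]), cc - (p[1] + t * v[1]))
    alpha = np.clip(radius + 0.5 - d, 0.0, 1.0)
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, background + alpha * (level - background), out=patch)


def _carve_pit(img: np.ndarray, center: np.ndarray, radius: float,
               background: float) -> None:
    # subtract a darker notch: pull intensity toward background inside the pit
    h, w = img.shape
    r0 = max(0, int(center[0] - radius - 2))
    r1 = min(h, int(center[0] + radius + 3))
    c0 = max(0, int(center[1] - radius - 2))
    c1 = min(w, int(center[1] + radius + 3))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - center[0], cc - center[1])
    alpha = np.clip(radius + 0.5 - d, 0.0, 1.0)
    patch = img[r0:r1, c0:c1]
    patch -= alpha * (patch - background)


def generate_eye_image(
    lattice: LatticeSpec,
    degeneration: DegenerationSpec | None = None,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a degenerating ommatidial array.

    Returns a float image in [0, 1] (bright dots on a darker background) and
    the ground truth (post-jitter centroids, fused pairs, pitted indices).
    Deterministic given the specs.
    """
    degeneration = degeneration or DegenerationSpec()
    rng = np.random.default_rng(degeneration.seed)
    h, w = lattice.shape
    base = hex_lattice_centroids(lattice)
    n = len(base)

    centroids = base.copy()
    clipped = False
    if degeneration.jitter_sd > 0:
        centroids = centroids + rng.normal(0.0, degeneration.jitter_sd, size=(n, 2))
        lo = lattice.dot_radius + 1.0
        hi = np.array([h, w], dtype=float) - lattice.dot_radius - 1.0
        clipped_mask = (centroids < lo) | (centroids > hi)
        if clipped_mask.any():
            clipped = True
            centroids = np.clip(centroids, lo, hi)

    # fusion: sample a matching over adjacent (pre-jitter) pairs
    fused_pairs: list[tuple[int, int]] = []
    if degeneration.fusion_rate > 0 and n > 1:
        d = np.linalg.norm(base[:, None, :] - base[None, :, :], axis=2)
        ii, jj = np.where((d > 0) & (d < 1.2 * lattice.spacing))
        pairs = [(int(a), int(b)) for a, b in zip(ii, jj) if a < b]
        order = rng.permutation(len(pairs))
        used: set[int] = set()
        for k in order:
            a, b = pairs[k]
            if a in used or b in used:
                continue
            if rng.random() < degeneration.fusion_rate:
                fused_pairs.append((a, b))
                used.add(a)
                used.add(b)
        fused_pairs.sort()

    pitted = [int(i) for i in np.where(rng.random(n) < degeneration.pit_rate)[0]]

    img = np.full((h, w), lattice.background_level, dtype=float)
    for c in centroids:
        _add_disk(img, c, lattice.dot_radius, lattice.dot_level,
                  lattice.background_level)
    bridge_r = 0.6 * lattice.dot_radius
    for a, b in fused_pairs:
        _add_capsule(img, centroids[a], centroids[b], bridge_r,
                     lattice.dot_level, lattice.background_level)
    pit_r = 0.45 * lattice.dot_radius
    for i in pitted:
        off = rng.uniform(-0.4 * lattice.dot_radius, 0.4 * lattice.dot_radius, 2)
        _carve_pit(img, centroids[i] + off, pit_r, lattice.background_level)

    if degeneration.noise_sd > 0:
        img = img + rng.normal(0.0, degeneration.noise_sd, img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    truth = SyntheticGroundTruth(
        true_centroids=centroids,
        true_count=n,
        fused_pairs=fused_pairs,
        pitted_indices=pitted,
        clipped=clipped,
    )
    return img, truth


# ---------------------------------------------------------------------------
# replicated line phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenoSimSpec:
    """Generative counterpart of the trait mixed model.

    Each replicate value is ``mu + group_offset + batch_offset + line_effect
    + residual`` with line effects ~ N(0, var_line) and residuals
    ~ N(0, var_residual).  Lines are assigned round-robin to groups; batches
    rotate across replicates within a line.
    """

    n_lines: int = 100
    reps_per_line: int = 10
    var_line: float = 1.0
    var_residual: float = 3.0
    mu: float = 0.0
    group_effects: dict[str, float] = field(default_factory=dict)
    batch_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.reps_per_line < 2:
            raise ValueError("need n_lines >= 2 and reps_per_line >= 2")
        if self.var_line < 0 or self.var_residual < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class SimulatedPhenotypes:
    data: pd.DataFrame  # columns: line, group, batch, value
    line_effects: pd.Series  # true random effects, indexed by line


def simulate_line_phenotypes(spec: PhenoSimSpec) -> SimulatedPhenotypes:
    rng = np.random.default_rng(spec.seed)
    lines = [f"line_{i:04d}" for i in range(spec.n_lines)]
    groups = list(spec.group_effects) or ["G1"]
    batches = list(spec.batch_effects) or ["B1"]
    u = rng.normal(0.0, math.sqrt(spec.var_line), spec.n_lines)

    rows = []
    for k, line in enumerate(lines):
        g = groups[k % len(groups)]
        g_eff = spec.group_effects.get(g, 0.0)
        for r in range(spec.reps_per_line):
            b = batches[(k + r) % len(batches)]
            b_eff = spec.batch_effects.get(b, 0.0)
            rows.append((line, g, b, spec.mu + g_eff + b_eff + u[k]))
    df = pd.DataFrame(rows, columns=["line", "group", "batch", "value"])
    df["value"] += rng.normal(0.0, math.sqrt(spec.var_residual), len(df))
    return SimulatedPhenotypes(
        data=df, line_effects=pd.Series(u, index=lines, name="line_effect")
    )


# ---------------------------------------------------------------------------
# genotype matrices for inbred line panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenoSimSpec:
    """Homozygous 0/1 genotype panel with structure and planted effects.

    Inbred lines carry no heterozygotes, so calls are the minor-homozygote
    class indicator.  Subpopulation structure follows a Balding-Nichols-like
    allele-frequency shift: subpopulation frequencies are Beta-distributed
    around the ancestral frequency with divergence ``fst_like_divergence``.
    """

    n_lines: int = 162
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_subpops: int = 1
    fst_like_divergence: float = 0.0
    causal_indices: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.causal_indices) != len(self.causal_effects):
            raise ValueError("causal_indices and causal_effects length mismatch")
        if any(i < 0 or i >= self.n_variants for i in self.causal_indices):
            raise ValueError("causal index out of range")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0.0 <= self.fst_like_divergence < 1.0:
            raise ValueError("fst_like_divergence must lie in [0, 1)")


def simulate_genotypes(spec: GenoSimSpec):
    """Returns (GenotypeMatrix, true_effects array of length n_variants)."""
    from .gwas import GenotypeMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    p_anc = rng.uniform(spec.maf_range[0], spec.maf_range[1], spec.n_variants)

    pops = np.arange(spec.n_lines) % spec.n_subpops
    f = spec.fst_like_divergence
    if spec.n_subpops > 1 and f > 0:
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pop_freq = np.stack(
            [np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4) for _ in range(spec.n_subpops)]
        )  # (n_subpops, n_variants)
    else:
        pop_freq = np.tile(p_anc, (spec.n_subpops, 1))

    calls = (rng.random((spec.n_lines, spec.n_variants)) < pop_freq[pops]).astype(float)
    if spec.missing_rate > 0:
        miss = rng.random(calls.shape) < spec.missing_rate
        calls[miss] = np.nan

    chroms = np.array(["2L", "2R", "3L", "3R", "X"])
    variants = pd.DataFrame(
        {
            "chrom": chroms[np.arange(spec.n_variants) % len(chroms)],
            "pos": 1000 + 100 * (np.arange(spec.n_variants) // len(chroms)),
            "id": [f"v{i:06d}" for i in range(spec.n_variants)],
            "type": "SNP",
        }
    )
    lines = [f"line_{i:04d}" for i in range(spec.n_lines)]
    true_effects = np.zeros(spec.n_variants)
    for i, e in zip(spec.causal_indices, spec.causal_effects):
        true_effects[i] = e
    return GenotypeMatrix(lines=lines, variants=variants, calls=calls), true_effects


def phenotype_from_genotypes(
    geno, effects: np.ndarray, noise_sd: float = 1.0, seed: int = 0
) -> pd.Series:
    """Additive per-line genetic value plus line-level noise.

    Missing calls contribute the variant's mean call (so planted effects stay
    additive in expectation).
    """
    rng = np.random.default_rng(seed)
    calls = geno.calls
    col_mean = np.nanmean(calls, axis=0)
    filled = np.where(np.isnan(calls), col_mean, calls)
    y = filled @ np.asarray(effects, dtype=float)
    y = y + rng.normal(0.0, noise_sd, len(y))
    return pd.Series(y, index=geno.lines, name="phenotype")


# ---------------------------------------------------------------------------
# ortholog / disease-catalog fixtures
# ---------------------------------------------------------------------------

def make_ortholog_fixture(
    n_fly_genes: int,
    n_pairs: int,
    n_ad_genes: int,
    planted_overlap: int,
    query_size: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str], list[str]]:
    """Toy ortholog table and disease catalog with a known planted overlap.

    Returns ``(pairs, catalog, query)`` such that exactly ``planted_overlap``
    pairs have fly gene in the query, confidence score >= 3 and human partner
    in the catalog.  Remaining pairs are built to contribute nothing to that
    count (non-query fly gene, non-catalog human partner, or score 2).
    """
    if planted_overlap > n_pairs:
        raise ValueError("planted_overlap cannot exceed n_pairs")
    if query_size > n_fly_genes:
        raise ValueError("query_size cannot exceed n_fly_genes")
    if n_ad_genes < 1:
        raise ValueError("catalog must contain at least one gene")
    if planted_overlap > 0 and query_size == 0:
        raise ValueError("cannot plant overlap with an empty query")

    rng = np.random.default_rng(seed)
    fly = [f"FBgn{i:07d}" for i in range(n_fly_genes)]
    query = fly[:query_size]
    n_human = max(n_ad_genes + 5, n_pairs + 5)
    human = [f"HGNC{i:05d}" for i in range(n_human)]
    catalog = set(human[:n_ad_genes])
    non_catalog = human[n_ad_genes:]

    rows = []
    for k in range(planted_overlap):
        rows.append(
            (query[k % query_size], human[k % n_ad_genes], int(rng.integers(3, 16)))
        )
    for k in range(n_pairs - planted_overlap):
        mode = rng.integers(0, 3)
        if mode == 0 and query_size < n_fly_genes:
            # non-query fly gene, any human, high score
            rows.append(
                (fly[query_size + k % (n_fly_genes - query_size)],
                 human[int(rng.integers(0, n_human))], int(rng.integers(3, 16)))
            )
        elif mode == 1 and non_catalog and query_size > 0:
            # query fly gene, non-catalog human, high score
            rows.append(
                (query[k % query_size],
                 non_catalog[int(rng.integers(0, len(non_catalog)))],
                 int(rng.integers(3, 16)))
            )
        else:
            # sub-threshold confidence score contributes nothing
            rows.append(
                (fly[int(rng.integers(0, n_fly_genes))],
                 human[int(rng.integers(0, n_human))], 2)
            )
    pairs = pd.DataFrame(rows, columns=["fly_gene", "human_gene", "score"])
    return pairs, catalog, query
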