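"""End-to-end orchestration: simulate -> quantify -> traits -> gwas -> enrich.

``run_full`` executes the whole flow on a synthetic bundle with a planted
causal variant: genotypes are simulated for an inbred panel, per-line
genetic liabilities derive replicate phenotypes (and scale the degeneration
of a demonstration image batch pushed through the full image pipeline), the
mixed model produces BLUPs, the association scan is run on them, suggestive
variants are mapped to a tiled synthetic gene annotation, and the mapped
gene set is tested for ortholog enrichment against a toy catalog.  Every
stage writes plain-text outputs plus a provenance record (config hash,
seeds, versions, per-stage row counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .enrichment import permutation_enrichment
from .gwas import AssociationScan, map_snps_to_genes
from .metrics import METRIC_NAMES, QuantifyConfig, quantify_image
from .simulate import (
    DegenerationSpec,
    GenoSimSpec,
    LatticeSpec,
    generate_eye_image,
    phenotype_from_genotypes,
    simulate_genotypes,
)
from .traits import LineBLUPModel

logger = logging.getLogger("flyeye")

__all__ = ["RunConfig", "run_image_batch", "run_full"]


def _from_dict(cls, d: dict):
    import typing

    hints = typing.get_type_hints(cls)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        ftype = hints.get(f.name, f.type)
        if dataclasses.is_dataclass(ftype) and isinstance(v, dict):
            v = _from_dict(ftype, v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class GenoStageConfig:
    n_lines: int = 80
    n_variants: int = 1500
    missing_rate: float = 0.02
    n_subpops: int = 2
    fst_like_divergence: float = 0.05
    causal_index: int = 700
    causal_effect: float = 1.0


@dataclass(frozen=True)
class PhenoStageConfig:
    reps_per_line: int = 6
    liability_noise_sd: float = 0.5  # line-level non-genetic variation
    residual_sd: float = 1.0  # replicate-level noise
    batch_effects: tuple[float, ...] = (0.0, 0.4)
    group_effects: tuple[float, ...] = (0.0, -0.3)


@dataclass(frozen=True)
class ImageStageConfig:
    enabled: bool = True
    n_image_lines: int = 6
    reps_per_line: int = 2
    n_rows: int = 7
    n_cols: int = 7
    spacing: float = 13.0
    dot_radius: float = 4.0
    structuring_radius: int = 7


@dataclass(frozen=True)
class GwasStageConfig:
    max_missing: float = 0.2
    min_maf: float = 0.05
    tw_alpha: float = 0.05
    alpha: float = 0.05
    suggestive_p: float = 1e-5


@dataclass(frozen=True)
class EnrichStageConfig:
    n_iter: int = 5000
    min_score: int = 3
    mode: str = "pairs"
    n_catalog_genes: int = 40
    pairs_per_gene: float = 0.6


@dataclass(frozen=True)
class RunConfig:
    """Full-run configuration; unknown keys are rejected on load."""

    seed: int = 0
    schema_version: int = 1
    geno: GenoStageConfig = field(default_factory=GenoStageConfig)
    pheno: PhenoStageConfig = field(default_factory=PhenoStageConfig)
    images: ImageStageConfig = field(default_factory=ImageStageConfig)
    gwas: GwasStageConfig = field(default_factory=GwasStageConfig)
    enrich: EnrichStageConfig = field(default_factory=EnrichStageConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _from_dict(cls, d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_image_batch(
    image_dir,
    metadata: pd.DataFrame,
    config: QuantifyConfig | None = None,
) -> pd.DataFrame:
    """Quantify every readable image in a directory.

    ``metadata`` maps ``image_id`` (file stem) to line/group/batch.  One
    metrics row per successfully processed image; failures are logged with
    the failing stage and the batch continues.
    """
    image_dir = Path(image_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no readable images in {image_dir}")
    meta = metadata.set_index("image_id") if "image_id" in metadata.columns else metadata
    rows = []
    n_failed = 0
    for p in paths:
        try:
            img = fio.read_image(p)
            ms = quantify_image(img, config)
        except Exception as exc:  # fault isolation: log and continue
            n_failed += 1
            logger.warning("failed to quantify %s: %s", p.name, exc)
            continue
        row = {"image_id": p.stem}
        if p.stem in meta.index:
            for col in ("line", "group", "batch"):
                if col in meta.columns:
                    row[col] = meta.loc[p.stem, col]
        row.update(ms.to_dict())
        rows.append(row)
    logger.info("quantified %d images (%d failures)", len(rows), n_failed)
    lead = ["image_id", "line", "group", "batch", "n_ommatidia"]
    cols = [c for c in lead if rows and c in rows[0]] + list(METRIC_NAMES)
    return pd.DataFrame(rows)[cols]


def _tiled_annotation(variants: pd.DataFrame, gene_span: int = 600) -> pd.DataFrame:
    """Synthetic gene annotation tiling the simulated chromosomes."""
    rows = []
    for chrom, sub in variants.groupby("chrom"):
        hi = int(sub["pos"].max()) + gene_span
        start = 1
        i = 0
        while start < hi:
            rows.append(
                {
                    "gene_id": f"{chrom}_g{i:04d}",
                    "symbol": f"{chrom}g{i}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_span - 1,
                    "strand": "+" if i % 2 == 0 else "-",
                }
            )
            start += gene_span
            i += 1
    return pd.DataFrame(rows)


def run_full(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns a results bundle of key objects/paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts: dict[str, int] = {}

    # --- stage 1: genotypes with a planted causal variant -----------------
    causal_index = config.geno.causal_index % config.geno.n_variants
    gspec = GenoSimSpec(
        n_lines=config.geno.n_lines,
        n_variants=config.geno.n_variants,
        missing_rate=config.geno.missing_rate,
        n_subpops=config.geno.n_subpops,
        fst_like_divergence=config.geno.fst_like_divergence,
        causal_indices=(causal_index,),
        causal_effects=(config.geno.causal_effect,),
        seed=int(rng.integers(2**31)),
    )
    geno, effects = simulate_genotypes(gspec)
    geno.to_tsv(outdir / "genotypes.tsv")
    counts["variants_simulated"] = geno.n_variants
    logger.info("stage simulate: %d lines x %d variants", geno.n_lines, geno.n_variants)

    # per-line genetic liability (causal genotype effect + line-level noise)
    liability = phenotype_from_genotypes(
        geno, effects, noise_sd=config.pheno.liability_noise_sd,
        seed=int(rng.integers(2**31)),
    )

    # --- stage 2: demonstration image batch ------------------------------
    if config.images.enabled:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        sev = liability.rank(pct=True)
        meta_rows = []
        lat = LatticeSpec(
            n_rows=config.images.n_rows, n_cols=config.images.n_cols,
            spacing=config.images.spacing, dot_radius=config.images.dot_radius,
        )
        for line in liability.index[: config.images.n_image_lines]:
            for rep in range(config.images.reps_per_line):
                deg = DegenerationSpec(
                    fusion_rate=0.35 * float(sev[line]),
                    pit_rate=0.4 * float(sev[line]),
                    jitter_sd=0.8 * float(sev[line]),
                    seed=int(rng.integers(2**31)),
                )
                img, truth = generate_eye_image(lat, deg)
                image_id = f"{line}_r{rep}"
                fio.write_image(img_dir / f"{image_id}.png", img)
                fio.write_ground_truth(img_dir / f"{image_id}.json", truth)
                meta_rows.append(
                    {"image_id": image_id, "line": line, "group": "G1",
                     "batch": f"B{rep % 2 + 1}"}
                )
        metadata = pd.DataFrame(meta_rows)
        fio.write_tsv(outdir / "image_metadata.tsv", metadata)
        qc = QuantifyConfig(structuring_radius=config.images.structuring_radius)
        img_metrics = run_image_batch(img_dir, metadata, qc)
        fio.write_tsv(outdir / "image_metrics.tsv", img_metrics)
        counts["images_quantified"] = len(img_metrics)

    # --- stage 3: replicate phenotypes and the mixed model ----------------
    batches = [f"B{i + 1}" for i in range(len(config.pheno.batch_effects))]
    groups = [f"G{i + 1}" for i in range(len(config.pheno.group_effects))]
    noise = np.random.default_rng(int(rng.integers(2**31)))
    rows = []
    for k, line in enumerate(liability.index):
        grp = groups[k % len(groups)]
        g_eff = config.pheno.group_effects[k % len(groups)]
        for r in range(config.pheno.reps_per_line):
            b = (k + r) % len(batches)
            rows.append(
                (line, grp, batches[b],
                 liability[line] + g_eff + config.pheno.batch_effects[b]
                 + noise.normal(0.0, config.pheno.residual_sd))
            )
    traits_df = pd.DataFrame(rows, columns=["line", "group", "batch", "value"])
    fio.write_tsv(outdir / "phenotypes.tsv", traits_df)
    model = LineBLUPModel().fit(traits_df)
    blups = model.blups_.set_index("line")
    fio.write_tsv(outdir / "blups.tsv", model.blups_)
    counts["lines_with_blups"] = len(blups)
    logger.info(
        "stage traits: var_line=%.3f var_resid=%.3f H2=%.3f",
        model.var_line_, model.var_residual_, model.h2_,
    )

    # --- stage 4: association scan ---------------------------------------
    scan = AssociationScan(
        max_missing=config.gwas.max_missing,
        min_maf=config.gwas.min_maf,
        tw_alpha=config.gwas.tw_alpha,
        alpha=config.gwas.alpha,
        suggestive_p=config.gwas.suggestive_p,
    ).fit(geno, blups[["blup"]].rename(columns={"blup": "degeneration"}))
    fio.write_tsv(outdir / "associations.tsv", scan.results_)
    fio.write_tsv(outdir / "hits_significant.tsv", scan.hits_.significant)
    fio.write_tsv(outdir / "hits_suggestive.tsv", scan.hits_.suggestive)
    counts["variants_tested"] = len(scan.results_)
    counts["significant_hits"] = scan.hits_.n_unique_significant
    counts["suggestive_hits"] = scan.hits_.n_unique_suggestive
    logger.info(
        "stage gwas: %d significant / %d suggestive unique variants",
        scan.hits_.n_unique_significant, scan.hits_.n_unique_suggestive,
    )

    # --- stage 5: gene mapping and ortholog enrichment --------------------
    annotation = _tiled_annotation(geno.variants)
    fio.write_tsv(outdir / "annotation.tsv", annotation)
    query: list[str] = []
    if len(scan.hits_.suggestive):
        assigned = map_snps_to_genes(scan.hits_.suggestive, annotation)
        fio.write_tsv(
            outdir / "suggestive_genes.tsv",
            assigned.assign(genes=assigned["genes"].map(",".join)),
        )
        query = sorted({g for gs in assigned["genes"] for g in gs})
    universe = list(annotation["gene_id"])

    erng = np.random.default_rng(int(rng.integers(2**31)))
    human = [f"HGNC{i:05d}" for i in range(max(200, config.enrich.n_catalog_genes * 3))]
    catalog = set(human[: config.enrich.n_catalog_genes])
    n_pairs = int(len(universe) * config.enrich.pairs_per_gene)
    pairs = pd.DataFrame(
        {
            "fly_gene": erng.choice(universe, size=n_pairs),
            "human_gene": erng.choice(human, size=n_pairs),
            "score": erng.integers(1, 16, size=n_pairs),
        }
    )
    fio.write_tsv(outdir / "ortholog_pairs.tsv", pairs)
    (outdir / "ad_catalog.txt").write_text("\n".join(sorted(catalog)) + "\n")
    enr = None
    if query:
        enr = permutation_enrichment(
            query, universe, pairs, catalog,
            n_iter=config.enrich.n_iter, seed=int(rng.integers(2**31)),
            min_score=config.enrich.min_score, mode=config.enrich.mode,
        )
        (outdir / "enrichment.json").write_text(
            json.dumps(
                {
                    "ho_obs": enr.ho_obs,
                    "null_mean": enr.null_mean,
                    "null_sd": enr.null_sd,
                    "p_value": enr.p_value,
                    "n_iter": enr.n_iter,
                    "mode": config.enrich.mode,
                },
                indent=1,
            )
        )
        counts["enrichment_query_genes"] = len(query)

    # --- provenance --------------------------------------------------------
    import flyeye

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "flyeye": flyeye.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": counts,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                       default=list))
    return {
        "genotypes": geno,
        "model": model,
        "scan": scan,
        "enrichment": enr,
        "provenance": provenance,
        "outdir": outdir,
    }
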