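"""Variant filtering, structure covariates, association scan and hit calling.

Inbred-line panels are homozygous, so genotypes are coded 0/1 (major/minor
homozygote class) and the additive model regresses per-line trait BLUPs on
the minor-class indicator plus covariates.  Population-structure covariates
are leading principal components of the standardised genotype matrix,
retained by a Tracy-Widom test on the eigenvalue spectrum (Patterson-style
normalisation, stop at the first non-significant eigenvalue).  Raw per-trait
P values are Benjamini-Hochberg adjusted; hits are classified as significant
(adjusted P < 0.05) or suggestive (raw P < 1e-5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "CovariateSet",
    "HitSet",
    "filter_variants",
    "pca_covariates",
    "tracy_widom_select",
    "associate",
    "bh_adjust",
    "classify_hits",
    "map_snps_to_genes",
    "AssociationScan",
]


@dataclass
class GenotypeMatrix:
    """Biallelic homozygous calls for an inbred line panel.

    ``calls`` is (n_lines, n_variants) float with values 0, 1 or NaN
    (missing).  Minor-allele frequency is computed over non-missing calls
    only; the coding is a class indicator, not an allele dosage, because
    inbred lines carry no heterozygotes.
    """

    lines: list[str]
    variants: pd.DataFrame  # columns: chrom, pos, id, type
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.lines), len(self.variants)):
            raise ValueError("calls shape does not match lines x variants")
        ok = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not ok.all():
            raise ValueError("calls must be 0, 1 or missing")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def maf(self) -> np.ndarray:
        freq = np.nanmean(self.calls, axis=0)
        return np.minimum(freq, 1.0 - freq)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            lines=list(self.lines),
            variants=self.variants.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask],
        )

    # -- plain-text round trips ------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.variants.copy()
        calls = self.calls.T
        for i, line in enumerate(self.lines):
            col = calls[:, i]
            df[line] = np.where(
                np.isnan(col), ".", np.nan_to_num(col).astype(int).astype(str)
            )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        meta = df[["chrom", "pos", "id", "type"]].copy()
        meta["pos"] = meta["pos"].astype(int)
        lines = [c for c in df.columns if c not in ("chrom", "pos", "id", "type")]
        calls = df[lines].replace(".", np.nan).astype(float).to_numpy().T
        return cls(lines=lines, variants=meta, calls=calls)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Minimal VCF reader: GT field, haploid or homozygous diploid."""
        rows, call_rows, lines = [], [], []
        with open(path) as fh:
            for text in fh:
                if text.startswith("##"):
                    continue
                parts = text.rstrip("\n").split("\t")
                if text.startswith("#CHROM"):
                    lines = parts[9:]
                    continue
                chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
                if "," in alt:
                    raise ValueError(f"multi-allelic record not supported: {vid}")
                vtype = "SNP"
                if len(ref) > len(alt):
                    vtype = "DEL"
                elif len(alt) > len(ref):
                    vtype = "INS"
                fmt = parts[8].split(":")
                gt_i = fmt.index("GT")
                row = []
                for sample in parts[9:]:
                    gt = sample.split(":")[gt_i].replace("|", "/")
                    alleles = {a for a in gt.split("/")}
                    if alleles <= {"."}:
                        row.append(np.nan)
                    elif alleles == {"0"}:
                        row.append(0.0)
                    elif alleles == {"1"}:
                        row.append(1.0)
                    else:
                        raise ValueError(
                            f"heterozygous or unsupported call '{gt}' at {vid}"
                        )
                rows.append((chrom, int(pos), vid, vtype))
                call_rows.append(row)
        variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "type"])
        calls = np.asarray(call_rows, dtype=float).T
        return cls(lines=lines, variants=variants, calls=calls)


@dataclass
class CovariateSet:
    """Structure covariates for the association model."""

    pcs: pd.DataFrame  # lines x retained PCs
    wolbachia: pd.Series | None = None
    n_pcs_retained: int = 0

    def matrix(self, lines: list[str]) -> np.ndarray:
        cols = []
        if self.n_pcs_retained > 0:
            cols.append(self.pcs.loc[lines].to_numpy()[:, : self.n_pcs_retained])
        if self.wolbachia is not None:
            cols.append(self.wolbachia.loc[lines].to_numpy(dtype=float)[:, None])
        if not cols:
            return np.empty((len(lines), 0))
        return np.column_stack(cols)


@dataclass
class HitSet:
    """Significant / suggestive classifications across traits."""

    significant: pd.DataFrame
    suggestive: pd.DataFrame
    trait_counts: pd.Series  # variant id -> number of traits suggestive
    n_unique_significant: int
    n_unique_suggestive: int


def filter_variants(
    g: GenotypeMatrix, max_missing: float = 0.2, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Discard variants with missing rate > max_missing or MAF < min_maf."""
    keep = (g.missing_rate() <= max_missing) & (g.maf() >= min_maf)
    if not keep.any():
        warnings.warn("no variants pass the filters", stacklevel=2)
    return g.subset_variants(keep)


@dataclass
class PCADecomposition:
    scores: pd.DataFrame  # lines x components
    eigenvalues: np.ndarray


def pca_covariates(g: GenotypeMatrix) -> PCADecomposition:
    """PCA of the standardised genotype matrix (mean-imputed missing calls).

    Eigenvalues are those of the line-by-line covariance of the
    standardised matrix, in non-increasing order.
    """
    calls = g.calls
    col_mean = np.nanmean(calls, axis=0)
    filled = np.where(np.isnan(calls), col_mean, calls)
    sd = filled.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.any():
        raise ValueError("zero-variance genotype matrix")
    Xs = (filled[:, ok] - filled[:, ok].mean(axis=0)) / sd[ok]
    Xc = Xs - Xs.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    evals = s**2 / (g.n_lines - 1)
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCADecomposition(
        scores=pd.DataFrame(scores, index=g.lines, columns=cols),
        eigenvalues=evals,
    )


# Tracy-Widom (TW1) upper-tail critical values, alpha -> quantile
_TW1_CRITICAL = {
    0.5: -1.2695,
    0.2: -0.1653,
    0.1: 0.4501,
    0.05: 0.9793,
    0.025: 1.4538,
    0.01: 2.0234,
    0.005: 2.4224,
    0.001: 3.2724,
}


def _tw_critical(alpha: float) -> float:
    if alpha >= 1.0:
        return -math.inf
    keys = sorted(_TW1_CRITICAL)
    if alpha in _TW1_CRITICAL:
        return _TW1_CRITICAL[alpha]
    if alpha >= keys[-1]:
        return _TW1_CRITICAL[keys[-1]]
    if alpha <= keys[0]:
        return _TW1_CRITICAL[keys[0]]
    # linear interpolation on log10(alpha) between tabulated points
    import bisect

    i = bisect.bisect_left(keys, alpha)
    a0, a1 = keys[i - 1], keys[i]
    t = (math.log10(alpha) - math.log10(a0)) / (math.log10(a1) - math.log10(a0))
    return _TW1_CRITICAL[a0] + t * (_TW1_CRITICAL[a1] - _TW1_CRITICAL[a0])


def tracy_widom_select(
    eigenvalues: np.ndarray, alpha: float = 0.05, max_pcs: int | None = None
) -> int:
    """Number of leading eigenvalues significant under the Tracy-Widom test.

    Each step normalises the remaining spectrum (effective-dimension
    estimate from its first two moments), forms the TW statistic for the
    leading eigenvalue and compares it with the alpha critical value;
    testing stops at the first non-significant eigenvalue.
    """
    evals = np.asarray(eigenvalues, dtype=float)
    evals = evals[evals > 1e-12]
    if evals.size == 0:
        raise ValueError("no positive eigenvalues to test")
    if max_pcs is None:
        max_pcs = len(evals) - 1
    if max_pcs > len(evals) - 1:
        raise ValueError("fewer eigenvalues than requested tests")
    crit = _tw_critical(alpha)
    n_kept = 0
    for i in range(max_pcs):
        rest = evals[i:]
        m = len(rest)
        if m < 2:
            break
        s1 = rest.sum()
        s2 = (rest**2).sum()
        denom = m * s2 - s1**2
        if denom <= 0:
            break  # spectrum too uniform for the effective-dimension estimate
        n_eff = m * s1**2 / denom
        if not np.isfinite(n_eff) or n_eff <= 1:
            break
        # rescale so the remaining spectrum has the trace of a white Wishart
        # with m eigenvalues and n_eff effective markers, then apply the
        # Johnstone centering/scaling for its largest eigenvalue
        lam1 = rest[0] * (m * n_eff) / s1
        sq_m = math.sqrt(m - 1)
        sq_n = math.sqrt(n_eff)
        mu = (sq_m + sq_n) ** 2
        sigma = (sq_m + sq_n) * (1.0 / sq_m + 1.0 / sq_n) ** (1.0 / 3.0)
        x = (lam1 - mu) / sigma
        if x > crit:
            n_kept += 1
        else:
            break
    return n_kept


def _ols_t_test(y: np.ndarray, g: np.ndarray, C: np.ndarray):
    """OLS of y on [1, g, C]; returns (beta_g, p) via the exact t test."""
    n = len(y)
    X = np.column_stack([np.ones(n), g, C])
    p = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p or n - p <= 0:
        return np.nan, np.nan
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0))
    if se == 0:
        return float(beta[1]), np.nan
    t = beta[1] / se
    return float(beta[1]), float(2.0 * stats.t.sf(abs(t), n - p))


def associate(
    trait_blups: pd.Series,
    g: GenotypeMatrix,
    cov: CovariateSet | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Per-variant linear additive association of BLUPs on minor-class calls.

    Lines with a missing call are dropped from that variant's regression
    (covariates themselves are complete).  Variants with too few usable
    lines are flagged untested (NaN beta/P).  Complete variants are
    processed in a vectorised residualisation pass; incomplete ones fall
    back to a per-variant solve.  The two paths compute the identical OLS
    t test on the allele coefficient.
    """
    y_full = trait_blups.loc[g.lines].to_numpy(dtype=float)
    C_full = cov.matrix(g.lines) if cov is not None else np.empty((g.n_lines, 0))
    n, k = g.calls.shape
    n_cov = C_full.shape[1]
    p_model = 2 + n_cov  # intercept + genotype + covariates

    beta = np.full(k, np.nan)
    pval = np.full(k, np.nan)
    n_used = np.zeros(k, dtype=int)

    missing_any = np.isnan(g.calls).any(axis=0)
    complete = ~missing_any
    n_used[complete] = n

    if complete.any() and n - p_model > 0:
        # Frisch-Waugh: residualise y and all complete genotype columns on
        # [1, C]; the genotype coefficient and its t statistic are unchanged.
        B = np.column_stack([np.ones(n), C_full])
        Q, _ = np.linalg.qr(B)
        G = g.calls[:, complete]
        y_r = y_full - Q @ (Q.T @ y_full)
        G_r = G - Q @ (Q.T @ G)
        gg = (G_r * G_r).sum(axis=0)
        gy = G_r.T @ y_full
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(gg > 1e-12, gy / gg, np.nan)
        dof = n - p_model
        rss = (y_r * y_r).sum() - np.where(np.isnan(b), 0.0, b * gy)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.maximum(rss / dof, 0.0) / gg)
            tstat = b / se
        pv = 2.0 * stats.t.sf(np.abs(tstat), dof)
        beta[complete] = b
        pval[complete] = np.where(np.isfinite(tstat), pv, np.nan)

    for j in np.where(missing_any)[0]:
        mask = ~np.isnan(g.calls[:, j])
        n_used[j] = int(mask.sum())
        if n_used[j] <= p_model:
            continue  # untested
        beta[j], pval[j] = _ols_t_test(
            y_full[mask], g.calls[mask, j], C_full[mask]
        )

    out = g.variants[["id", "chrom", "pos"]].copy()
    out.insert(0, "trait", trait)
    out = out.rename(columns={"id": "variant"})
    out["beta"] = beta
    out["p_raw"] = pval
    out["n_used"] = n_used
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_hits(
    records: pd.DataFrame,
    alpha: float = 0.05,
    suggestive_p: float = 1e-5,
    adjust_scope: str = "within-trait",
) -> HitSet:
    """BH-adjust and classify association records across traits.

    ``adjust_scope`` is ``"within-trait"`` (each trait's scan adjusted
    separately; the default) or ``"global"`` (one adjustment over the pooled
    records).  Untested records (NaN P) are excluded from adjustment and
    from both hit sets.
    """
    df = records.copy()
    tested = df["p_raw"].notna()
    df["p_adjust"] = np.nan
    if adjust_scope == "within-trait":
        for _, idx in df.loc[tested].groupby("trait").groups.items():
            df.loc[idx, "p_adjust"] = bh_adjust(df.loc[idx, "p_raw"].to_numpy())
    elif adjust_scope == "global":
        df.loc[tested, "p_adjust"] = bh_adjust(df.loc[tested, "p_raw"].to_numpy())
    else:
        raise ValueError("adjust_scope must be 'within-trait' or 'global'")

    significant = df[df["p_adjust"] < alpha].copy()
    suggestive = df[df["p_raw"] < suggestive_p].copy()
    trait_counts = (
        suggestive.groupby("variant")["trait"].nunique().sort_values(ascending=False)
    )
    return HitSet(
        significant=significant,
        suggestive=suggestive,
        trait_counts=trait_counts,
        n_unique_significant=significant["variant"].nunique(),
        n_unique_suggestive=suggestive["variant"].nunique(),
    )


def map_snps_to_genes(
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 0,
) -> pd.DataFrame:
    """Assign each variant all genes overlapping it within +/- window bp.

    ``annotation`` needs columns gene_id, symbol, chrom, start, end (1-based
    inclusive).  The primary gene of a multi-gene locus is the one with the
    smallest start (ties broken by lexicographic gene_id); variants with no
    overlapping gene are flagged intergenic.
    """
    if (annotation["start"] > annotation["end"]).any():
        raise ValueError("malformed annotation interval (start > end)")
    by_chrom = {c: sub.sort_values(["start", "gene_id"]) for c, sub in
                annotation.groupby("chrom")}
    rows = []
    for _, v in variants.iterrows():
        sub = by_chrom.get(v["chrom"])
        if sub is None:
            genes = []
        else:
            hit = sub[(sub["start"] - window <= v["pos"]) &
                      (v["pos"] <= sub["end"] + window)]
            genes = list(hit["gene_id"])
        rows.append(
            {
                "variant": v["variant"] if "variant" in v else v["id"],
                "chrom": v["chrom"],
                "pos": v["pos"],
                "genes": genes,
                "primary_gene": genes[0] if genes else None,
                "intergenic": len(genes) == 0,
            }
        )
    return pd.DataFrame(rows)


class AssociationScan(BaseEstimator):
    """Filter -> structure covariates -> per-trait scan -> BH -> hits.

    ``fit`` takes a genotype matrix and a DataFrame of per-line BLUPs (index
    = lines, one column per trait), optionally a per-line binary infection
    status to include as a covariate.  Fitted attributes: ``filtered_``,
    ``covariates_``, ``results_`` and ``hits_``.
    """

    def __init__(
        self,
        max_missing: float = 0.2,
        min_maf: float = 0.05,
        tw_alpha: float = 0.05,
        alpha: float = 0.05,
        suggestive_p: float = 1e-5,
        adjust_scope: str = "within-trait",
    ):
        self.max_missing = max_missing
        self.min_maf = min_maf
        self.tw_alpha = tw_alpha
        self.alpha = alpha
        self.suggestive_p = suggestive_p
        self.adjust_scope = adjust_scope

    def fit(
        self,
        X: GenotypeMatrix,
        y: pd.DataFrame,
        wolbachia: pd.Series | None = None,
    ):
        g = filter_variants(X, self.max_missing, self.min_maf)
        self.filtered_ = g
        if g.n_variants == 0:
            warnings.warn("empty scan after filtering", stacklevel=2)
            self.covariates_ = CovariateSet(
                pcs=pd.DataFrame(index=g.lines), wolbachia=wolbachia,
                n_pcs_retained=0,
            )
            self.results_ = pd.DataFrame(
                columns=["trait", "variant", "chrom", "pos", "beta", "p_raw",
                         "n_used"]
            )
            self.hits_ = classify_hits(
                self.results_.assign(p_raw=pd.Series(dtype=float)),
                self.alpha, self.suggestive_p, self.adjust_scope,
            )
            return self
        pca = pca_covariates(g)
        n_pcs = tracy_widom_select(pca.eigenvalues, alpha=self.tw_alpha)
        self.pca_ = pca
        self.covariates_ = CovariateSet(
            pcs=pca.scores, wolbachia=wolbachia, n_pcs_retained=n_pcs
        )
        blups = y if isinstance(y, pd.DataFrame) else y.to_frame()
        results = [
            associate(blups[trait], g, self.covariates_, trait=trait)
            for trait in blups.columns
        ]
        self.results_ = pd.concat(results, ignore_index=True)
        self.hits_ = classify_hits(
            self.results_, self.alpha, self.suggestive_p, self.adjust_scope
        )
        return self
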