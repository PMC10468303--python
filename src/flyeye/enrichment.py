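"""Cross-species ortholog-set enrichment by permutation.

Given a query set of fly genes (e.g. genes mapped by suggestive GWAS
variants), count how many fly-human ortholog pairs (confidence score >= 3)
have their human partner in a disease-association catalog, and compare that
count with the null distribution obtained by repeatedly drawing random fly
gene sets of the same size from the genome-wide universe.

Because ortholog relationships are many-to-many, "how many orthologs are
disease-associated" is ambiguous: the counting unit can be pairs or distinct
human genes.  Both modes are implemented and the mode is an explicit
required choice on the counting function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PermutationResult",
    "count_ad_orthologs",
    "permutation_enrichment",
    "PermutationEnrichment",
]


@dataclass
class PermutationResult:
    ho_obs: int
    ho_perm: np.ndarray
    n_iter: int
    p_value: float

    def __post_init__(self) -> None:
        self.ho_perm = np.asarray(self.ho_perm)
        assert len(self.ho_perm) == self.n_iter
        assert 0.0 <= self.p_value <= 1.0

    @property
    def null_mean(self) -> float:
        return float(self.ho_perm.mean())

    @property
    def null_sd(self) -> float:
        return float(self.ho_perm.std(ddof=1)) if self.n_iter > 1 else 0.0


def count_ad_orthologs(
    fly_genes: set[str],
    pairs: pd.DataFrame,
    catalog: set[str],
    min_score: int = 3,
    mode: str = "pairs",
) -> int:
    """Disease-linked ortholog count for a fly gene set.

    ``mode="pairs"`` counts fly-human pairs; ``mode="human_genes"`` counts
    distinct human genes (collapsing duplicated partners across pairs).
    Only pairs with score >= ``min_score`` participate.
    """
    if mode not in ("pairs", "human_genes"):
        raise ValueError("mode must be 'pairs' or 'human_genes'")
    hit = pairs[
        (pairs["score"] >= min_score)
        & pairs["fly_gene"].isin(fly_genes)
        & pairs["human_gene"].isin(catalog)
    ]
    if mode == "pairs":
        return int(len(hit))
    return int(hit["human_gene"].nunique())


def permutation_enrichment(
    query_genes: list[str] | set[str],
    universe: list[str],
    pairs: pd.DataFrame,
    catalog: set[str],
    n_iter: int = 10_000,
    seed: int = 0,
    min_score: int = 3,
    mode: str = "pairs",
    add_one: bool = True,
) -> PermutationResult:
    """Permutation test for ortholog-set enrichment.

    Each of ``n_iter`` iterations draws (without replacement) a random fly
    gene set of the query's size from ``universe`` and scores it with
    :func:`count_ad_orthologs`.  The default P value uses the add-one rule
    P = (1 + #{perm >= obs}) / (1 + n_iter); ``add_one=False`` gives the
    plain proportion #{perm >= obs} / n_iter.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    query = set(query_genes)
    if len(query) > len(universe):
        raise ValueError("query size exceeds universe size")
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(list(universe))
    k = len(query)

    ho_obs = count_ad_orthologs(query, pairs, catalog, min_score, mode)

    scored = pairs[(pairs["score"] >= min_score) & pairs["human_gene"].isin(catalog)]
    if mode == "pairs":
        # pair counts are additive over fly genes: precompute per-gene weights
        weight_by_gene = scored.groupby("fly_gene").size()
        weights = (
            weight_by_gene.reindex(universe_arr).fillna(0).to_numpy(dtype=np.int64)
        )
        ho_perm = np.empty(n_iter, dtype=np.int64)
        m = len(universe_arr)
        for i in range(n_iter):
            idx = rng.choice(m, size=k, replace=False)
            ho_perm[i] = weights[idx].sum()
    else:
        humans_by_gene = {
            g: frozenset(sub["human_gene"]) for g, sub in scored.groupby("fly_gene")
        }
        ho_perm = np.empty(n_iter, dtype=np.int64)
        for i in range(n_iter):
            sample = rng.choice(universe_arr, size=k, replace=False)
            seen: set[str] = set()
            for gene in sample:
                hs = humans_by_gene.get(gene)
                if hs:
                    seen.update(hs)
            ho_perm[i] = len(seen)

    n_ge = int((ho_perm >= ho_obs).sum())
    if add_one:
        p = (1 + n_ge) / (1 + n_iter)
    else:
        p = n_ge / n_iter
    return PermutationResult(ho_obs=ho_obs, ho_perm=ho_perm, n_iter=n_iter,
                             p_value=float(p))


class PermutationEnrichment(BaseEstimator):
    """Estimator wrapper over :func:`permutation_enrichment`.

    ``fit(query, universe, pairs, catalog)`` exposes ``ho_obs_``,
    ``null_mean_``, ``null_sd_``, ``p_value_`` and ``result_``.
    """

    def __init__(
        self,
        n_iter: int = 10_000,
        seed: int = 0,
        min_score: int = 3,
        mode: str = "pairs",
        add_one: bool = True,
    ):
        self.n_iter = n_iter
        self.seed = seed
        self.min_score = min_score
        self.mode = mode
        self.add_one = add_one

    def fit(self, X, y=None, *, universe=None, pairs=None, catalog=None):
        if universe is None or pairs is None or catalog is None:
            raise ValueError("universe, pairs and catalog are required")
        res = permutation_enrichment(
            X, universe, pairs, catalog,
            n_iter=self.n_iter, seed=self.seed, min_score=self.min_score,
            mode=self.mode, add_one=self.add_one,
        )
        self.result_ = res
        self.ho_obs_ = res.ho_obs
        self.null_mean_ = res.null_mean
        self.null_sd_ = res.null_sd
        self.p_value_ = res.p_value
        return self
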