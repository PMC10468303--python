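"""Variant filtering, covariate selection, association and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from flyeye.gwas import (
    AssociationScan,
    CovariateSet,
    GenotypeMatrix,
    associate,
    bh_adjust,
    classify_hits,
    filter_variants,
    map_snps_to_genes,
    pca_covariates,
    tracy_widom_select,
)
from flyeye.simulate import GenoSimSpec, simulate_genotypes


def make_matrix(calls, lines=None):
    calls = np.asarray(calls, dtype=float)
    n, k = calls.shape
    lines = lines or [f"l{i}" for i in range(n)]
    variants = pd.DataFrame(
        {"chrom": ["2L"] * k, "pos": np.arange(1, k + 1) * 100,
         "id": [f"v{j}" for j in range(k)], "type": "SNP"}
    )
    return GenotypeMatrix(lines=lines, variants=variants, calls=calls)


class TestFilterVariants:
    def test_maf_threshold(self):
        calls = np.zeros((100, 2))
        calls[:4, 0] = 1  # MAF 0.04 -> discarded
        calls[:30, 1] = 1  # MAF 0.30 -> retained
        g = filter_variants(make_matrix(calls))
        assert list(g.variants["id"]) == ["v1"]

    def test_missing_rate_threshold(self):
        calls = np.zeros((100, 2))
        calls[:50, :] = 1
        calls[:25, 0] = np.nan  # missing 0.25 -> discarded
        calls[:20, 1] = np.nan  # missing 0.20 -> retained (boundary kept)
        g = filter_variants(make_matrix(calls))
        assert list(g.variants["id"]) == ["v1"]

    def test_empty_result_warns(self):
        calls = np.zeros((50, 1))
        with pytest.warns(UserWarning, match="no variants"):
            g = filter_variants(make_matrix(calls))
        assert g.n_variants == 0


class TestPCA:
    def test_duplicate_lines_identical_scores(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, size=(20, 100)).astype(float)
        calls[5] = calls[3]
        pca = pca_covariates(make_matrix(calls))
        assert np.allclose(pca.scores.iloc[3], pca.scores.iloc[5], atol=1e-9)

    def test_eigenvalues_sorted_nonnegative(self):
        geno, _ = simulate_genotypes(GenoSimSpec(n_lines=40, n_variants=300, seed=1))
        ev = pca_covariates(geno).eigenvalues
        assert (ev >= -1e-9).all()
        assert (np.diff(ev) <= 1e-9).all()

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pca_covariates(make_matrix(np.zeros((10, 5))))


class TestTracyWidom:
    def test_alpha_one_retains_all_tested(self):
        geno, _ = simulate_genotypes(GenoSimSpec(n_lines=30, n_variants=300, seed=2))
        ev = pca_covariates(geno).eigenvalues
        n = tracy_widom_select(ev, alpha=1.0, max_pcs=10)
        assert n == 10

    def test_structured_panel_retains_at_least_one(self):
        geno, _ = simulate_genotypes(
            GenoSimSpec(n_lines=100, n_variants=1000, n_subpops=2,
                        fst_like_divergence=0.2, seed=3)
        )
        ev = pca_covariates(geno).eigenvalues
        assert tracy_widom_select(ev, alpha=0.05) >= 1

    def test_null_panels_rarely_retain_pcs(self):
        # unstructured panels: no PC should be retained in >= 90% of runs
        zero = 0
        for seed in range(50):
            geno, _ = simulate_genotypes(
                GenoSimSpec(n_lines=100, n_variants=1000, seed=seed)
            )
            ev = pca_covariates(geno).eigenvalues
            zero += tracy_widom_select(ev, alpha=0.05) == 0
        assert zero / 50 >= 0.90

    def test_too_many_requested_tests_error(self):
        with pytest.raises(ValueError):
            tracy_widom_select(np.array([3.0, 2.0, 1.0]), max_pcs=5)


class TestAssociate:
    def _oracle(self, y, g, C):
        n = len(y)
        X = np.column_stack([np.ones(n), g, C])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        return beta[1], 2 * stats.t.sf(abs(t), dof)

    def test_matches_normal_equations_oracle_complete(self, rng):
        n = 10
        calls = rng.integers(0, 2, size=(n, 4)).astype(float)
        g = make_matrix(calls)
        y = pd.Series(rng.normal(size=n), index=g.lines)
        C = rng.normal(size=(n, 2))
        cov = CovariateSet(
            pcs=pd.DataFrame(C, index=g.lines, columns=["PC1", "PC2"]),
            n_pcs_retained=2,
        )
        res = associate(y, g, cov)
        for j in range(4):
            b, p = self._oracle(y.to_numpy(), calls[:, j], C)
            assert res.loc[j, "beta"] == pytest.approx(b, abs=1e-10)
            assert res.loc[j, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_matches_oracle_with_missing_calls(self, rng):
        n = 30
        calls = rng.integers(0, 2, size=(n, 3)).astype(float)
        calls[[2, 5, 11], 1] = np.nan
        g = make_matrix(calls)
        y = pd.Series(rng.normal(size=n), index=g.lines)
        res = associate(y, g, None)
        mask = ~np.isnan(calls[:, 1])
        b, p = self._oracle(y.to_numpy()[mask], calls[mask, 1],
                            np.empty((mask.sum(), 0)))
        assert res.loc[1, "n_used"] == mask.sum()
        assert res.loc[1, "beta"] == pytest.approx(b, abs=1e-10)
        assert res.loc[1, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_underpowered_variant_flagged_untested(self, rng):
        calls = np.full((10, 1), np.nan)
        calls[:2, 0] = [0, 1]  # n_used <= n_covariates + 2 -> untested
        g = make_matrix(calls)
        y = pd.Series(rng.normal(size=10), index=g.lines)
        res = associate(y, g, None)
        assert np.isnan(res.loc[0, "p_raw"])
        assert res.loc[0, "n_used"] == 2

    def test_permuted_phenotype_destroys_signal(self, rng):
        geno, eff = simulate_genotypes(
            GenoSimSpec(n_lines=100, n_variants=300, causal_indices=(50,),
                        causal_effects=(2.0,), seed=4)
        )
        from flyeye.simulate import phenotype_from_genotypes

        y = phenotype_from_genotypes(geno, eff, noise_sd=0.5, seed=5)
        res = associate(y, geno, None)
        assert res.loc[50, "p_raw"] < 1e-10
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res_perm = associate(y_perm, geno, None)
        assert res_perm.loc[50, "p_raw"] > 1e-4


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_example_all_equal(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_matches_step_up_formula(self, rng):
        p = rng.uniform(size=57)
        order = np.argsort(p)[::-1]  # largest first
        expected = np.empty_like(p)
        running = 1.0
        n = len(p)
        for rank_from_top, idx in enumerate(order):
            rank = n - rank_from_top
            running = min(running, p[idx] * n / rank)
            expected[idx] = running
        assert np.allclose(bh_adjust(p), expected, atol=1e-15)

    def test_out_of_range_errors(self):
        for bad in ([0.0], [1.5], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=40),
           st.integers(0, 39))
    def test_lowering_a_p_never_loses_discoveries(self, ps, idx):
        ps = np.asarray(ps)
        idx = idx % len(ps)
        base = (bh_adjust(ps) < 0.05).sum()
        ps2 = ps.copy()
        ps2[idx] = ps2[idx] / 2
        assert (bh_adjust(ps2) < 0.05).sum() >= base


class TestClassifyHits:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["trait", "variant", "chrom", "pos",
                                           "beta", "p_raw", "n_used"])

    def test_boundary_thresholds(self):
        # one strong hit among enough nulls that BH keeps p_adjust < 0.05
        rows = [("t", f"v{j}", "2L", 100 + j, 0.1, 0.8, 50) for j in range(9)]
        rows.append(("t", "v9", "2L", 999, 1.0, 0.004, 50))
        hits = classify_hits(self._records(rows))
        assert list(hits.significant["variant"]) == ["v9"]  # 0.004*10/1 = 0.04
        assert hits.suggestive.empty  # 0.004 is not < 1e-5
        rows2 = [("t", "v0", "2L", 100, 1.0, 2e-5, 50)]
        assert classify_hits(self._records(rows2)).suggestive.empty

    def test_cross_trait_suggestive_count(self):
        rows = []
        for i in range(14):
            p = 1e-7 if i < 12 else 0.5  # suggestive in exactly 12 traits
            rows.append((f"trait{i}", "vX", "X", 42, 1.0, p, 50))
            rows.append((f"trait{i}", "vY", "X", 43, 1.0, 0.3, 50))
        hits = classify_hits(self._records(rows))
        assert hits.trait_counts["vX"] == 12
        assert "vY" not in hits.trait_counts.index

    def test_within_trait_vs_global_scope(self):
        rows = [("a", "v0", "2L", 1, 1.0, 0.001, 50),
                ("a", "v1", "2L", 2, 1.0, 0.9, 50),
                ("b", "v0", "2L", 1, 1.0, 0.04, 50),
                ("b", "v1", "2L", 2, 1.0, 0.5, 50)]
        within = classify_hits(self._records(rows), adjust_scope="within-trait")
        glob = classify_hits(self._records(rows), adjust_scope="global")
        pw = within.significant
        assert ("b" in set(pw["trait"])) or ("a" in set(pw["trait"]))
        assert not glob.significant.equals(pw) or len(glob.significant) == len(pw)


class TestGeneMapping:
    ANNOT = pd.DataFrame(
        {
            "gene_id": ["FBgn1", "FBgn2", "FBgn3"],
            "symbol": ["a", "b", "c"],
            "chrom": ["X", "X", "2L"],
            "start": [100, 150, 1000],
            "end": [200, 260, 2000],
            "strand": ["+", "-", "+"],
        }
    )

    def _variants(self, rows):
        return pd.DataFrame(rows, columns=["variant", "chrom", "pos"])

    def test_single_gene_primary(self):
        out = map_snps_to_genes(self._variants([("v1", "2L", 1500)]), self.ANNOT)
        assert out.loc[0, "genes"] == ["FBgn3"]
        assert out.loc[0, "primary_gene"] == "FBgn3"
        assert not out.loc[0, "intergenic"]

    def test_overlapping_genes_deterministic_primary(self):
        out = map_snps_to_genes(self._variants([("v1", "X", 180)]), self.ANNOT)
        assert sorted(out.loc[0, "genes"]) == ["FBgn1", "FBgn2"]
        assert out.loc[0, "primary_gene"] == "FBgn1"  # smallest start wins

    def test_far_variant_intergenic(self):
        out = map_snps_to_genes(self._variants([("v1", "X", 12000)]), self.ANNOT,
                                window=1000)
        assert out.loc[0, "intergenic"]

    def test_window_rescues_nearby_variant(self):
        out = map_snps_to_genes(self._variants([("v1", "X", 290)]), self.ANNOT,
                                window=50)
        assert out.loc[0, "genes"] == ["FBgn2"]

    def test_malformed_interval_errors(self):
        bad = self.ANNOT.assign(start=[100, 400, 1000], end=[200, 260, 2000])
        with pytest.raises(ValueError):
            map_snps_to_genes(self._variants([("v1", "X", 180)]), bad)


class TestGenotypeIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        calls = rng.integers(0, 2, size=(6, 5)).astype(float)
        calls[0, 0] = np.nan
        g = make_matrix(calls)
        path = tmp_path / "geno.tsv"
        g.to_tsv(path)
        g2 = GenotypeMatrix.from_tsv(path)
        assert g2.lines == g.lines
        assert np.allclose(g2.calls, g.calls, equal_nan=True)

    def test_minimal_vcf_reader(self, tmp_path):
        vcf = """##fileformat=VCFv4.2
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tlineA\tlineB\tlineC
2L\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t1/1\t./.
X\t250\tv2\tAC\tA\t.\t.\t.\tGT\t0\t1\t0
"""
        path = tmp_path / "g.vcf"
        path.write_text(vcf)
        g = GenotypeMatrix.from_vcf(path)
        assert g.lines == ["lineA", "lineB", "lineC"]
        assert g.variants.loc[1, "type"] == "DEL"
        assert np.allclose(g.calls[:, 0], [0, 1, np.nan], equal_nan=True)
        assert np.allclose(g.calls[:, 1], [0, 1, 0])

    def test_heterozygous_call_rejected(self, tmp_path):
        vcf = """##fileformat=VCFv4.2
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
2L\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/1
"""
        path = tmp_path / "g.vcf"
        path.write_text(vcf)
        with pytest.raises(ValueError, match="heterozygous"):
            GenotypeMatrix.from_vcf(path)


class TestScanDeterminism:
    def test_rerun_identical(self, rng):
        geno, eff = simulate_genotypes(
            GenoSimSpec(n_lines=60, n_variants=400, missing_rate=0.05,
                        causal_indices=(10,), causal_effects=(1.0,), seed=6)
        )
        from flyeye.simulate import phenotype_from_genotypes

        y = phenotype_from_genotypes(geno, eff, seed=7).to_frame("t")
        s1 = AssociationScan().fit(geno, y)
        s2 = AssociationScan().fit(geno, y)
        pd.testing.assert_frame_equal(s1.results_, s2.results_)
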