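"""QC, GRM, PCA, relatedness pruning, REML variance components."""

import numpy as np
import pandas as pd
import pytest

from triarchy import genetics, simulate
from triarchy.genetics import GenotypeMatrix


def make_geno(dosages):
    n, m = dosages.shape
    variants = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(m)], "chrom": "1",
        "bp": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "G",
    })
    return GenotypeMatrix(dosages=dosages.astype(float), variants=variants,
                          subjects=[f"S{i}" for i in range(n)])


class TestQC:
    def test_low_maf_removed(self):
        rng = np.random.default_rng(0)
        n = 500
        dos = np.column_stack([
            rng.binomial(2, 0.04, n),  # MAF ~0.04 -> dropped at 0.05
            rng.binomial(2, 0.3, n),
        ]).astype(float)
        out, report = genetics.qc_genotypes(make_geno(dos), maf_min=0.05)
        assert out.n_snps == 1 and report.n_removed_maf >= 1

    def test_exact_hwe_retained(self):
        dos = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)])
        out, _ = genetics.qc_genotypes(make_geno(dos[:, None]))
        assert out.n_snps == 1

    def test_hwe_violation_removed(self):
        # all heterozygous: strongly violates HWE
        dos = np.ones((500, 1))
        with pytest.raises(ValueError):  # only SNP removed -> empty panel
            genetics.qc_genotypes(make_geno(dos))

    def test_monomorphic_removed(self):
        rng = np.random.default_rng(1)
        dos = np.column_stack([np.zeros(200), rng.binomial(2, 0.3, 200)]).astype(float)
        out, _ = genetics.qc_genotypes(make_geno(dos))
        assert out.n_snps == 1

    def test_high_missingness_snp_and_subject(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.3, (100, 20)).astype(float)
        dos[:20, 0] = np.nan  # 20% missing SNP
        dos[0, 1:] = np.nan  # subject missing nearly everything
        out, report = genetics.qc_genotypes(make_geno(dos))
        assert report.n_removed_miss == 1
        assert report.n_subjects_removed == 1


class TestGRM:
    def test_two_subject_hand_example(self):
        # one SNP with sample freq 0.5: dosages 0 and 2 give A_12 = -1/0.5 = -2
        A = genetics.compute_grm(np.array([[0.0], [2.0]]))
        assert A[0, 1] == pytest.approx(-2.0)

    def test_centered_dosage_zero_diagonal(self):
        # dosage equal to 2p at every SNP contributes nothing
        dos = np.array([[1.0, 1.0], [0.0, 2.0], [2.0, 0.0]])
        A = genetics.compute_grm(dos)
        assert A[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_unrelated_cohort_moments(self, small_genotypes):
        dosages, W, p = small_genotypes
        A = genetics.compute_grm(dosages)
        assert 0.98 <= np.mean(np.diag(A)) <= 1.02
        off = A[np.triu_indices_from(A, 1)]
        assert abs(np.mean(off)) < 0.005

    def test_mean_imputation_matches_explicit(self, small_genotypes):
        dosages, _, _ = small_genotypes
        dos = dosages[:, :50].copy()
        rng = np.random.default_rng(3)
        miss = rng.random(dos.shape) < 0.05
        dos[miss] = np.nan
        A = genetics.compute_grm(dos)
        assert np.isfinite(A).all()


class TestPruneAndPCA:
    def test_no_pairs_above_cutoff(self):
        A = np.eye(5)
        assert len(genetics.prune_related(A, 0.05, seed=0)) == 5

    def test_one_related_pair_drops_one(self):
        A = np.eye(6)
        A[1, 4] = A[4, 1] = 0.3
        kept = genetics.prune_related(A, 0.05, seed=0)
        assert len(kept) == 5 and ({1, 4} - set(kept))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        A = np.eye(20) + 0.0
        for i, j in [(0, 1), (5, 9), (12, 13)]:
            A[i, j] = A[j, i] = 0.4
        k1 = genetics.prune_related(A, 0.05, seed=7)
        k2 = genetics.prune_related(A, 0.05, seed=7)
        assert np.array_equal(k1, k2)

    def test_pcs_orthonormal(self, small_genotypes):
        dosages, _, _ = small_genotypes
        A = genetics.compute_grm(dosages)
        pcs = genetics.grm_pca(A, k=5).to_numpy()
        assert np.allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)

    def test_two_population_structure_separated(self):
        rng = np.random.default_rng(5)
        m = 400
        p1 = rng.uniform(0.1, 0.5, m)
        p2 = np.clip(p1 + rng.normal(0, 0.12, m), 0.05, 0.95)
        dos = np.vstack([
            rng.binomial(2, p1, (150, m)),
            rng.binomial(2, p2, (150, m)),
        ]).astype(float)
        A = genetics.compute_grm(dos)
        pc1 = genetics.grm_pca(A, k=2)["PC1"].to_numpy()
        labels = np.repeat([0.0, 1.0], 150)
        assert abs(np.corrcoef(pc1, labels)[0, 1]) > 0.9

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            genetics.grm_pca(np.eye(3), k=5)


class TestREML:
    def test_recovery_of_planted_h2(self, small_genotypes):
        dosages, W, p = small_genotypes
        A = W @ W.T / W.shape[1]
        d, U = np.linalg.eigh(A)
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(15):
            y = simulate.planted_trait(W[:, rng.choice(W.shape[1], 80, replace=False)], 0.5, rng)
            vc = genetics.reml_variance_components(y, [A], eigen=(d, U))
            hits += abs(vc.h2 - 0.5) <= 2 * vc.h2_se
        assert hits >= 13

    def test_null_trait_near_boundary(self, small_genotypes):
        dosages, W, _ = small_genotypes
        A = W @ W.T / W.shape[1]
        d, U = np.linalg.eigh(A)
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(12):
            y = rng.standard_normal(A.shape[0])
            vc = genetics.reml_variance_components(y, [A], eigen=(d, U))
            pvals.append(vc.lrt_p)
        assert np.mean(np.array(pvals) > 0.05) >= 0.75

    def test_grid_search_oracle_agreement(self):
        rng = np.random.default_rng(8)
        n, m = 200, 400
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), (n, m)).astype(float)
        A = genetics.compute_grm(dos)
        W = genetics.standardized_dosages(dos)
        y = simulate.planted_trait(W[:, :50], 0.5, rng)
        vc = genetics.reml_variance_components(y, [A])
        X = np.ones((n, 1))
        # two-stage grid around the AI-REML solution
        s_hat = vc.variance_components
        grid = np.linspace(0.5, 1.5, 41)
        best = -np.inf
        for a in grid:
            for b in grid:
                ll = genetics.reml_loglik_dense(y, [A], X, np.array([a * s_hat[0], b * s_hat[1]]))
                best = max(best, ll)
        assert vc.loglik >= best - 1e-4
        assert abs(vc.loglik - best) < 1e-3

    def test_loglik_monotone_over_iterations(self, small_genotypes):
        dosages, W, _ = small_genotypes
        A = W @ W.T / W.shape[1]
        rng = np.random.default_rng(9)
        y = simulate.planted_trait(W[:, :60], 0.4, rng)
        vc = genetics.reml_variance_components(y, [A])
        h = np.array(vc.loglik_history)
        assert (np.diff(h) >= -1e-6).all()

    def test_covariates_absorbed(self, small_genotypes):
        dosages, W, _ = small_genotypes
        A = W @ W.T / W.shape[1]
        rng = np.random.default_rng(10)
        cov = rng.standard_normal((A.shape[0], 2))
        y = simulate.planted_trait(W[:, :60], 0.5, rng) + cov @ np.array([1.0, -0.5])
        vc = genetics.reml_variance_components(y, [A], covariates=cov)
        assert abs(vc.h2 - 0.5) <= 3 * vc.h2_se


class TestBivariate:
    def test_identical_traits_rg_one(self, small_genotypes):
        dosages, W, _ = small_genotypes
        A = W @ W.T / W.shape[1]
        rng = np.random.default_rng(11)
        y = simulate.planted_trait(W[:, :80], 0.5, rng)
        bv = genetics.reml_bivariate(y, y.copy(), A)
        assert bv.rg == pytest.approx(1.0, abs=1e-3)

    def test_planted_rg_recovered(self, small_genotypes):
        dosages, W, _ = small_genotypes
        A = W @ W.T / W.shape[1]
        d, U = np.linalg.eigh(A)
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(10):
            y1, y2 = simulate.planted_trait_pair(
                W[:, rng.choice(W.shape[1], 80, replace=False)], 0.5, 0.5, 0.5, rng)
            bv = genetics.reml_bivariate(y1, y2, A, eigen=(d, U))
            hits += abs(bv.rg - 0.5) <= 2 * (bv.rg_se or np.inf)
        assert hits >= 8

    def test_independent_architectures_rg_near_zero(self, small_genotypes):
        dosages, W, _ = small_genotypes
        A = W @ W.T / W.shape[1]
        d, U = np.linalg.eigh(A)
        rng = np.random.default_rng(13)
        rgs = []
        for _ in range(8):
            y1, y2 = simulate.planted_trait_pair(
                W[:, rng.choice(W.shape[1], 80, replace=False)], 0.5, 0.5, 0.0, rng)
            rgs.append(genetics.reml_bivariate(y1, y2, A, eigen=(d, U)).rg)
        assert abs(np.mean(rgs)) < 0.25


class TestPartition:
    def test_concentrated_set_enriched(self, small_genotypes):
        dosages, W, _ = small_genotypes
        m = W.shape[1]
        set_mask = np.zeros(m, bool)
        set_mask[:80] = True  # 10% of SNPs
        rng = np.random.default_rng(14)
        y = simulate.planted_trait(W[:, :60], 0.5, rng)  # causal inside the set
        pr = genetics.partition_enrichment(y, set_mask, dosages)
        assert pr.fold > 3.0 and pr.p < 0.05

    def test_uniform_trait_fold_near_one(self, small_genotypes):
        dosages, W, _ = small_genotypes
        m = W.shape[1]
        set_mask = np.zeros(m, bool)
        set_mask[::4] = True
        rng = np.random.default_rng(15)
        y = simulate.planted_trait(W, 0.5, rng)  # every SNP causal
        pr = genetics.partition_enrichment(y, set_mask, dosages)
        assert 0.4 < pr.fold < 2.5

    def test_additivity_against_single_grm(self, small_genotypes):
        dosages, W, _ = small_genotypes
        rng = np.random.default_rng(16)
        y = simulate.planted_trait(W[:, :200], 0.5, rng)
        single = genetics.reml_variance_components(y, [W @ W.T / W.shape[1]])
        set_mask = np.zeros(W.shape[1], bool)
        set_mask[:400] = True
        pr = genetics.partition_enrichment(y, set_mask, dosages)
        assert abs(pr.h2_total - single.h2) <= 2 * single.h2_se + 0.1

    def test_degenerate_set_rejected(self, small_genotypes):
        dosages, _, _ = small_genotypes
        with pytest.raises(ValueError):
            genetics.partition_enrichment(np.zeros(dosages.shape[0]),
                                          np.zeros(dosages.shape[1], bool), dosages)
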