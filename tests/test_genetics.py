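"""Genotype/sample QC and C+T polygenic scoring."""

import numpy as np
import pandas as pd
import pytest

import pgsmediate as pm
from pgsmediate.genetics import (
    GenotypeTable,
    GwasSummary,
    hwe_chi2_p,
    inbreeding_coefficient,
    pi_hat_matrix,
)


def make_genotypes(dosage: np.ndarray, snp_prefix="rs") -> GenotypeTable:
    n, m = dosage.shape
    snps = [f"{snp_prefix}{j}" for j in range(m)]
    return GenotypeTable(
        dosage=pd.DataFrame(
            dosage.astype(float), index=[f"P{i}" for i in range(n)], columns=snps
        ),
        meta=pd.DataFrame(
            {"effect_allele": "A", "other_allele": "G"},
            index=pd.Index(snps, name="snp"),
        ),
    )


def hwe_genotypes(rng, n, mafs) -> GenotypeTable:
    return make_genotypes(rng.binomial(2, mafs[None, :], size=(n, mafs.size)))


class TestSnpQc:
    def test_low_maf_snp_removed(self, rng):
        mafs = np.array([0.3, 0.3, 0.3])
        geno = hwe_genotypes(rng, 2000, mafs)
        # overwrite one column with MAF 0.04
        geno.dosage.iloc[:, 1] = rng.binomial(2, 0.04, 2000).astype(float)
        out = pm.snp_qc(geno)
        assert list(out.dosage.columns) == ["rs0", "rs2"]

    def test_all_heterozygous_fails_hwe(self, rng):
        """100 participants all heterozygous: chi-square = n = 100,
        p << 1e-6, so the SNP is dropped."""
        d = np.ones((100, 2))
        d[:, 1] = rng.binomial(2, 0.5, 100)
        geno = make_genotypes(d)
        assert hwe_chi2_p(np.ones(100)) < 1e-20
        out = pm.snp_qc(geno)
        assert "rs0" not in out.dosage.columns

    def test_missingness_above_two_percent_removed(self, rng):
        geno = hwe_genotypes(rng, 100, np.full(2, 0.4))
        geno.dosage.iloc[:3, 0] = np.nan  # 3% missing
        out = pm.snp_qc(geno)
        assert list(out.dosage.columns) == ["rs1"]

    def test_idempotent(self, rng):
        geno = hwe_genotypes(rng, 300, rng.uniform(0.02, 0.5, 40))
        once = pm.snp_qc(geno)
        twice = pm.snp_qc(once)
        assert list(once.dosage.columns) == list(twice.dosage.columns)

    def test_all_removed_raises(self, rng):
        geno = hwe_genotypes(rng, 200, np.full(3, 0.01))
        with pytest.raises(ValueError, match="all SNPs"):
            pm.snp_qc(geno)


class TestSampleQc:
    def test_fully_missing_participant_removed(self, rng):
        geno = hwe_genotypes(rng, 50, rng.uniform(0.2, 0.5, 100))
        geno.dosage.iloc[7] = np.nan
        kept = pm.sample_qc(geno)
        assert "P7" not in kept

    def test_hwe_cohort_mostly_retained(self, rng):
        geno = hwe_genotypes(rng, 500, rng.uniform(0.1, 0.5, 2000))
        f = inbreeding_coefficient(geno)
        assert abs(f.mean()) < 0.02
        kept = pm.sample_qc(geno)
        assert len(kept) >= 495

    def test_fully_homozygous_participant_removed(self, rng):
        geno = hwe_genotypes(rng, 100, rng.uniform(0.3, 0.5, 2000))
        d = geno.dosage.to_numpy()
        d[5] = np.where(d[5] == 1.0, 2.0, d[5])  # erase every heterozygote
        f = inbreeding_coefficient(make_genotypes(d))
        assert f.iloc[5] > 0.9
        kept = pm.sample_qc(make_genotypes(d))
        assert "P5" not in kept


class TestRelatedness:
    def test_duplicate_participant_flagged_and_one_removed(self, rng):
        d = rng.binomial(2, np.full(800, 0.35), size=(40, 800)).astype(float)
        d[13] = d[4]
        geno = make_genotypes(d)
        pihat = pi_hat_matrix(geno)
        assert pihat.iloc[4, 13] > 0.8  # ~1 up to sampling noise
        kept = pm.relatedness_filter(geno, random_state=0)
        assert ("P4" in kept) != ("P13" in kept)

    def test_parent_offspring_pihat_half(self, rng):
        """A child sharing exactly one allele per SNP with the parent gives
        pi-hat ~ 0.5."""
        m = 2000
        p = np.full(m, 0.4)
        mother = rng.binomial(2, p, m)
        father = rng.binomial(2, p, m)
        m_allele = np.where(mother == 1, rng.integers(0, 2, m), mother // 2)
        f_allele = np.where(father == 1, rng.integers(0, 2, m), father // 2)
        child = m_allele + f_allele
        others = rng.binomial(2, p, size=(20, m))
        d = np.vstack([mother, child, others]).astype(float)
        pihat = pi_hat_matrix(make_genotypes(d))
        assert pihat.iloc[0, 1] == pytest.approx(0.5, abs=0.1)
        kept = pm.relatedness_filter(make_genotypes(d), random_state=1)
        assert ("P0" in kept) != ("P1" in kept)

    def test_unrelated_cohort_not_touched(self, rng):
        geno = hwe_genotypes(rng, 60, rng.uniform(0.25, 0.5, 3000))
        kept = pm.relatedness_filter(geno, random_state=0)
        assert len(kept) == 60


class TestPcOutliers:
    def test_homogeneous_cohort_keeps_everyone(self, rng):
        geno = hwe_genotypes(rng, 120, rng.uniform(0.1, 0.5, 600))
        kept, pcs = pm.pc_outlier_filter(geno, n_pcs=20)
        assert len(kept) == 120
        assert list(pcs.columns) == ["PC1", "PC2", "PC3", "PC4"]

    def test_planted_ancestry_outlier_removed(self, rng):
        mafs = rng.uniform(0.2, 0.5, 800)
        d = rng.binomial(2, mafs[None, :], size=(100, 800)).astype(float)
        shifted = np.clip(mafs + 0.45, 0.01, 0.99)
        d[42] = rng.binomial(2, shifted)
        kept, _ = pm.pc_outlier_filter(make_genotypes(d), n_pcs=20)
        assert "P42" not in kept

    def test_pc_scores_orthogonal(self, rng):
        geno = hwe_genotypes(rng, 80, rng.uniform(0.1, 0.5, 400))
        _, pcs = pm.pc_outlier_filter(geno, n_pcs=10)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_rank_limit_enforced(self, rng):
        geno = hwe_genotypes(rng, 10, rng.uniform(0.2, 0.5, 50))
        with pytest.raises(ValueError, match="rank"):
            pm.pc_outlier_filter(geno, n_pcs=30)


class TestScoring:
    def make_gwas(self, snps, betas, ps, effect="A", other="G"):
        return GwasSummary(
            pd.DataFrame(
                {
                    "snp": snps,
                    "effect_allele": effect,
                    "other_allele": other,
                    "beta": betas,
                    "p": ps,
                }
            )
        )

    def test_weighted_sum_arithmetic(self):
        geno = make_genotypes(np.array([[2.0, 1.0]]))
        gwas = self.make_gwas(["rs0", "rs1"], [0.5, -1.0], [0.01, 0.01])
        score = pm.compute_pgs(geno, gwas, p_threshold=0.05)
        assert score.iloc[0] == pytest.approx(0.0)

    def test_threshold_below_all_p_raises(self):
        geno = make_genotypes(np.array([[1.0, 2.0]]))
        gwas = self.make_gwas(["rs0", "rs1"], [0.5, 0.5], [0.2, 0.3])
        with pytest.raises(ValueError, match="no SNP"):
            pm.compute_pgs(geno, gwas, p_threshold=0.1)

    def test_allele_harmonization_identity(self, rng):
        geno = hwe_genotypes(rng, 50, np.full(4, 0.4))
        betas = rng.normal(0, 1, 4)
        g1 = self.make_gwas(list(geno.dosage.columns), betas, [0.01] * 4)
        # swap allele labels and negate betas for SNP 2
        t = g1.table.copy()
        t.loc[2, ["effect_allele", "other_allele"]] = ["G", "A"]
        t.loc[2, "beta"] = -t.loc[2, "beta"]
        g2 = GwasSummary(t)
        s1 = pm.compute_pgs(geno, g1, 0.05)
        s2 = pm.compute_pgs(geno, g2, 0.05)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_score_invariant_to_snp_order(self, rng):
        geno = hwe_genotypes(rng, 30, rng.uniform(0.2, 0.5, 6))
        betas = rng.normal(0, 1, 6)
        gwas = self.make_gwas(list(geno.dosage.columns), betas, [0.01] * 6)
        shuffled = GwasSummary(gwas.table.sample(frac=1, random_state=3).reset_index(drop=True))
        np.testing.assert_allclose(
            pm.compute_pgs(geno, gwas, 1.0).to_numpy(),
            pm.compute_pgs(geno, shuffled, 1.0).to_numpy(),
        )

    def test_missing_dosage_imputed_with_mean(self, rng):
        d = rng.binomial(2, np.full(1, 0.5), size=(10, 1)).astype(float)
        d[0, 0] = np.nan
        geno = make_genotypes(d)
        gwas = self.make_gwas(["rs0"], [1.0], [0.01])
        score = pm.compute_pgs(geno, gwas, 0.05)
        assert score.iloc[0] == pytest.approx(np.nanmean(d) / 2 * 2)

    def test_info_filter_drops_low_quality(self):
        t = pd.DataFrame(
            {
                "snp": ["rs0", "rs1"],
                "effect_allele": "A",
                "other_allele": "G",
                "beta": [0.1, 0.2],
                "p": [0.5, 0.5],
                "info": [0.95, 0.5],
            }
        )
        assert list(GwasSummary(t).filter_info().table["snp"]) == ["rs0"]


class TestThresholdSearch:
    def _null_setup(self, rng, n=150, m=100):
        geno = hwe_genotypes(rng, n, rng.uniform(0.1, 0.5, m))
        gwas = GwasSummary(
            pd.DataFrame(
                {
                    "snp": list(geno.dosage.columns),
                    "effect_allele": "A",
                    "other_allele": "G",
                    "beta": rng.normal(0, 0.1, m),
                    "p": rng.uniform(0, 1, m),
                }
            )
        )
        cov = pd.DataFrame(
            {
                "age": rng.uniform(20, 70, n),
                "sex": rng.integers(0, 2, n).astype(float),
            },
            index=geno.dosage.index,
        )
        return geno, gwas, cov

    def test_increments_nonnegative_and_best_attains_max(self, rng):
        geno, gwas, cov = self._null_setup(rng)
        res = pm.threshold_search(
            geno, gwas, rng.normal(0, 1, 150), cov, n_permutations=0
        )
        finite = res.r2_increments[np.isfinite(res.r2_increments)]
        assert np.all(finite >= -1e-15)
        assert res.best_r2_increment == pytest.approx(np.nanmax(res.r2_increments))

    def test_no_permutations_gives_no_corrected_p(self, rng):
        geno, gwas, cov = self._null_setup(rng)
        res = pm.threshold_search(
            geno, gwas, rng.normal(0, 1, 150), cov, n_permutations=0
        )
        assert res.permutation_p is None

    def test_corrected_p_bounds(self, rng):
        geno, gwas, cov = self._null_setup(rng)
        res = pm.threshold_search(
            geno, gwas, rng.normal(0, 1, 150), cov, n_permutations=50, random_state=0
        )
        assert 1 / 51 <= res.permutation_p <= 1.0

    def test_planted_signal_found_at_low_threshold(self):
        cfg = pm.CohortConfig(
            n_participants=1500,
            n_snps=600,
            n_causal_snps=120,
            h2_pgs=0.05,
            mediator_rois=(),
            bands=("theta",),
            seed=5,
        )
        from pgsmediate.simulate import _child_rngs, _compose_g, simulate_covariates

        rg, rc, _, rgg, _ = _child_rngs(5, 5)
        geno, gwas, score = pm.simulate_genetics(cfg, rg)
        cov = simulate_covariates(cfg, rc)
        g, _ = _compose_g(score, None, cfg, rgg)
        res = pm.threshold_search(
            geno,
            gwas,
            g,
            cov[["age", "sex", "PC1", "PC2", "PC3", "PC4"]],
            n_permutations=100,
            random_state=5,
        )
        assert res.best_threshold <= 1e-2
        assert res.best_r2_increment > 0.02
        assert res.permutation_p == pytest.approx(1 / 101)


class TestLdClump:
    def test_independent_snps_all_kept(self, rng):
        geno = hwe_genotypes(rng, 400, rng.uniform(0.2, 0.5, 30))
        from pgsmediate.genetics import GwasSummary, ld_clump

        gwas = GwasSummary(
            pd.DataFrame(
                {
                    "snp": list(geno.dosage.columns),
                    "effect_allele": "A",
                    "other_allele": "G",
                    "beta": rng.normal(0, 0.1, 30),
                    "p": rng.uniform(0, 1, 30),
                }
            )
        )
        kept = ld_clump(geno, gwas, r2_max=0.1)
        assert len(kept) >= 28  # chance r^2 above 0.1 is rare at n=400

    def test_duplicated_snp_clumped_keeping_lower_p(self, rng):
        d = rng.binomial(2, np.full(10, 0.4), size=(300, 10)).astype(float)
        d[:, 7] = d[:, 2]  # perfect LD pair
        geno = make_genotypes(d)
        from pgsmediate.genetics import GwasSummary, ld_clump

        p = np.linspace(0.1, 0.9, 10)
        p[7], p[2] = 0.01, 0.5  # rs7 is the stronger signal of the pair
        gwas = GwasSummary(
            pd.DataFrame(
                {
                    "snp": list(geno.dosage.columns),
                    "effect_allele": "A",
                    "other_allele": "G",
                    "beta": 0.1,
                    "p": p,
                }
            )
        )
        kept = ld_clump(geno, gwas, r2_max=0.1)
        assert "rs7" in kept and "rs2" not in kept
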