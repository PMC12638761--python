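"""Genotype/sample quality control and clumping-and-thresholding polygenic
scores.

QC mirrors the standard PLINK-style pipeline: per-SNP filters on minor
allele frequency, Hardy-Weinberg equilibrium (1-df chi-square) and
missingness; per-sample filters on missingness and the method-of-moments
inbreeding coefficient F; relatedness exclusion on a high-quality SNP
subset via pairwise pi-hat; and principal-component outlier removal with
the first four PCs exported as ancestry covariates.

Scoring is C+T: the score is the allele-dosage-weighted sum of GWAS effect
sizes over SNPs whose published p-value passes a threshold; the threshold
is searched over a dense grid for the largest R^2 increment over a
covariate-only regression of the phenotype, and the winning model's
p-value is corrected by phenotype-permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GenotypeTable",
    "GwasSummary",
    "PgsResult",
    "snp_qc",
    "sample_qc",
    "relatedness_filter",
    "pc_outlier_filter",
    "ld_clump",
    "compute_pgs",
    "PgsThresholdSearch",
    "threshold_search",
    "hwe_chi2_p",
]


@dataclass
class GenotypeTable:
    """Dosage matrix (participants x SNPs, 0/1/2 with NaN for missing) plus
    per-SNP allele metadata."""

    dosage: pd.DataFrame
    meta: pd.DataFrame  # index = SNP id; columns effect_allele, other_allele

    def __post_init__(self):
        if not self.dosage.columns.equals(self.meta.index):
            self.meta = self.meta.loc[self.dosage.columns]
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_participants(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_frequency(self) -> pd.Series:
        """Frequency of the effect allele from non-missing dosages."""
        return self.dosage.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        af = self.allele_frequency()
        return np.minimum(af, 1.0 - af)

    def snp_missingness(self) -> pd.Series:
        return self.dosage.isna().mean(axis=0)

    def sample_missingness(self) -> pd.Series:
        return self.dosage.isna().mean(axis=1)

    def subset(self, participants=None, snps=None) -> "GenotypeTable":
        d = self.dosage
        if participants is not None:
            d = d.loc[participants]
        if snps is not None:
            d = d[snps]
        return GenotypeTable(d, self.meta.loc[d.columns])


@dataclass
class GwasSummary:
    """Per-SNP external association results: effect allele, beta, p."""

    table: pd.DataFrame  # columns snp, effect_allele, other_allele, beta, p

    def __post_init__(self):
        required = {"snp", "effect_allele", "other_allele", "beta", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"gwas table lacks columns {sorted(missing)}")
        if self.table["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids in summary statistics")
        p = self.table["p"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    def filter_info(self, min_info: float = 0.9) -> "GwasSummary":
        """Drop SNPs with imputation INFO below threshold, if the column exists."""
        if "info" not in self.table.columns:
            return self
        return GwasSummary(self.table[self.table["info"] > min_info].reset_index(drop=True))


# ---------------------------------------------------------------------------
# QC


def hwe_chi2_p(dosage_column: np.ndarray) -> float:
    """1-df chi-square Hardy-Weinberg test p-value for one SNP's dosages."""
    d = dosage_column[~np.isnan(dosage_column)]
    n = d.size
    if n == 0:
        return 1.0
    counts = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()], dtype=float)
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p <= 0 or p >= 1:
        return 1.0  # monomorphic: HWE vacuous
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    genotypes: GenotypeTable,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    miss_max: float = 0.02,
) -> GenotypeTable:
    """Remove SNPs failing MAF, HWE or missingness filters."""
    if genotypes.n_participants < 2:
        raise ValueError("SNP QC needs at least 2 participants")
    maf_ok = genotypes.maf() >= maf_min
    miss_ok = genotypes.snp_missingness() <= miss_max
    vals = genotypes.dosage.to_numpy(dtype=float)
    hwe_p = np.array([hwe_chi2_p(vals[:, j]) for j in range(vals.shape[1])])
    hwe_ok = pd.Series(hwe_p >= hwe_p_min, index=genotypes.dosage.columns)
    keep = maf_ok & miss_ok & hwe_ok
    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    return genotypes.subset(snps=genotypes.dosage.columns[keep])


def inbreeding_coefficient(genotypes: GenotypeTable) -> pd.Series:
    """Method-of-moments F per participant: 1 - observed/expected heterozygosity."""
    d = genotypes.dosage.to_numpy(dtype=float)
    af = genotypes.allele_frequency().to_numpy()
    exp_het = 2.0 * af * (1.0 - af)
    observed = np.where(np.isnan(d), 0.0, (d == 1.0).astype(float)).sum(axis=1)
    expected = (~np.isnan(d)).astype(float) @ exp_het
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - observed / expected
    f = np.where(expected > 0, f, np.nan)
    return pd.Series(f, index=genotypes.dosage.index, name="F")


def sample_qc(
    genotypes: GenotypeTable, miss_max: float = 0.02, het_limit: float = 0.2
) -> pd.Index:
    """Participants passing missingness and heterozygosity (|F|) filters."""
    miss = genotypes.sample_missingness()
    f = inbreeding_coefficient(genotypes)
    keep = (miss <= miss_max) & (f.abs() <= het_limit) & f.notna()
    return genotypes.dosage.index[keep]


def pi_hat_matrix(genotypes: GenotypeTable) -> pd.DataFrame:
    """Pairwise relatedness (pi-hat) by the method-of-moments genomic
    relationship estimator: the average of
    ``(x_i - 2p)(x_j - 2p) / (2p(1-p))`` over SNPs estimates 2*kinship,
    which is ~1 for duplicates, ~0.5 for parent-offspring, ~0 for
    unrelated pairs.  Missing dosages are mean-imputed."""
    d = genotypes.dosage.to_numpy(dtype=float)
    af = genotypes.allele_frequency().to_numpy()
    usable = (af > 0) & (af < 1)
    d = d[:, usable]
    af = af[usable]
    centered = np.where(np.isnan(d), 0.0, d - 2 * af)
    scale = np.sqrt(2 * af * (1 - af))
    z = centered / scale
    grm = (z @ z.T) / z.shape[1]
    ids = genotypes.dosage.index
    return pd.DataFrame(grm, index=ids, columns=ids)


def relatedness_filter(
    genotypes: GenotypeTable,
    pihat_max: float = 0.2,
    hq_maf_min: float = 0.2,
    hq_hwe_p_min: float = 0.02,
    random_state: int | np.random.Generator | None = 0,
) -> pd.Index:
    """Drop one random member of every pair with pi-hat above threshold.

    Pi-hat is computed on a high-genotyping-quality SNP subset (MAF above
    ``hq_maf_min``, HWE p above ``hq_hwe_p_min``, zero missingness).
    """
    rng = np.random.default_rng(random_state) if not isinstance(
        random_state, np.random.Generator
    ) else random_state
    maf = genotypes.maf()
    miss = genotypes.snp_missingness()
    vals = genotypes.dosage.to_numpy(dtype=float)
    hwe_p = np.array([hwe_chi2_p(vals[:, j]) for j in range(vals.shape[1])])
    hq = (maf > hq_maf_min) & (miss == 0) & (hwe_p > hq_hwe_p_min)
    subset = genotypes.subset(snps=genotypes.dosage.columns[hq]) if hq.any() else genotypes
    pihat = pi_hat_matrix(subset)
    ids = list(pihat.index)
    mat = pihat.to_numpy()
    removed: set = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if mat[i, j] > pihat_max and ids[i] not in removed and ids[j] not in removed:
                removed.add(ids[i] if rng.random() < 0.5 else ids[j])
    return pd.Index([x for x in ids if x not in removed])


def pc_outlier_filter(
    genotypes: GenotypeTable,
    sd_limit: float = 4.5,
    n_pcs: int = 20,
    n_covariate_pcs: int = 4,
) -> tuple[pd.Index, pd.DataFrame]:
    """Remove ancestry outliers on the leading PCs; export covariate PCs.

    Dosages are mean-imputed (for the PCA only), centred and scaled; a
    participant is removed when any of the first ``n_pcs`` standardized PC
    scores exceeds ``sd_limit`` in absolute value.  Returns (kept ids, PC
    score table with columns PC1..PC{n_covariate_pcs} for all input
    participants).
    """
    d = genotypes.dosage.to_numpy(dtype=float)
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean, d)
    centered = filled - filled.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    keep_cols = sd > 0
    z = centered[:, keep_cols] / sd[keep_cols]
    max_rank = min(z.shape[0] - 1, z.shape[1])
    if n_pcs > max_rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank {max_rank}")
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    zs = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    outlier = (np.abs(zs) > sd_limit).any(axis=1)
    kept = genotypes.dosage.index[~outlier]
    pcs = pd.DataFrame(
        scores[:, :n_covariate_pcs],
        index=genotypes.dosage.index,
        columns=[f"PC{i + 1}" for i in range(n_covariate_pcs)],
    )
    return kept, pcs


# ---------------------------------------------------------------------------
# polygenic scoring


def _harmonize(genotypes: GenotypeTable, gwas: GwasSummary) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Intersect SNPs and orient betas to the genotype effect allele.

    A summary-statistics SNP whose effect allele matches the genotype
    effect allele keeps its beta; a swapped pair flips the sign; an
    irreconcilable allele pair is dropped.
    """
    g = gwas.table.set_index("snp")
    common = genotypes.dosage.columns.intersection(g.index)
    if common.empty:
        raise ValueError("no SNPs shared between genotypes and summary statistics")
    meta = genotypes.meta.loc[common]
    gsub = g.loc[common]
    same = (gsub["effect_allele"].to_numpy() == meta["effect_allele"].to_numpy()) & (
        gsub["other_allele"].to_numpy() == meta["other_allele"].to_numpy()
    )
    flipped = (gsub["effect_allele"].to_numpy() == meta["other_allele"].to_numpy()) & (
        gsub["other_allele"].to_numpy() == meta["effect_allele"].to_numpy()
    )
    usable = same | flipped
    snps = common[usable]
    beta = np.where(same[usable], 1.0, -1.0) * gsub["beta"].to_numpy()[usable]
    p = gsub["p"].to_numpy()[usable]
    return genotypes.dosage[snps], beta, p


def _imputed_dosage(dosage: pd.DataFrame) -> np.ndarray:
    d = dosage.to_numpy(dtype=float)
    af = np.nanmean(d, axis=0) / 2.0
    return np.where(np.isnan(d), 2.0 * af, d)


def ld_clump(
    genotypes: GenotypeTable, gwas: GwasSummary, r2_max: float = 0.1
) -> pd.Index:
    """Greedy LD clumping: walk SNPs by ascending association p and keep a
    SNP only if its dosage r^2 with every already-kept SNP stays below
    ``r2_max``.  Returns the kept SNP ids (use with ``subset`` before
    scoring).  Synthetic SNPs are independent, so this is off by default in
    the pipeline and intended for real dosage data."""
    g = gwas.table.set_index("snp")
    common = genotypes.dosage.columns.intersection(g.index)
    order = g.loc[common, "p"].sort_values(kind="stable").index
    d = _imputed_dosage(genotypes.dosage[order])
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    d = d / np.where(sd > 0, sd, 1.0)
    n = d.shape[0]
    kept: list[int] = []
    for j in range(d.shape[1]):
        if all((d[:, j] @ d[:, k] / n) ** 2 < r2_max for k in kept):
            kept.append(j)
    return pd.Index(order[kept])


def compute_pgs(
    genotypes: GenotypeTable, gwas: GwasSummary, p_threshold: float
) -> pd.Series:
    """Weighted allele-dosage sum over SNPs with published p <= threshold."""
    dosage, beta, p = _harmonize(genotypes, gwas)
    mask = p <= p_threshold
    if not mask.any():
        raise ValueError(f"no SNP passes p-threshold {p_threshold}")
    d = _imputed_dosage(dosage.iloc[:, :])[:, mask]
    score = d @ beta[mask]
    return pd.Series(score, index=genotypes.dosage.index, name="pgs")


@dataclass
class PgsResult:
    thresholds: np.ndarray
    r2_increments: np.ndarray
    best_threshold: float
    best_r2_increment: float
    best_score: pd.Series
    permutation_p: float | None
    n_permutations: int


class PgsThresholdSearch(BaseEstimator):
    """Best-fit C+T polygenic score with permutation-corrected p-value.

    For thresholds on a dense grid (default 5e-5 to 1 in steps of 5e-5),
    the score over SNPs passing each threshold is entered into a linear
    regression of the phenotype on the covariates, and the threshold with
    the largest R^2 increment over the covariate-only model wins.  Because
    the winner is optimized, its p-value is corrected by re-running the full
    search on phenotype permutations: corrected
    p = (1 + #{permuted max increment >= observed}) / (B + 1).

    Scores are updated incrementally over SNPs sorted by p, so the search
    costs one cumulative sum plus one residualized correlation per distinct
    threshold.
    """

    def __init__(
        self,
        grid_step: float = 5e-5,
        n_permutations: int = 1000,
        random_state: int | None = 0,
    ):
        self.grid_step = grid_step
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X: GenotypeTable, y, *, gwas: GwasSummary, covariates: pd.DataFrame):
        """sklearn-style entry point; the GWAS table and covariates travel as
        fit keywords because they are data, not hyperparameters."""
        return self.fit_with_gwas(X, gwas, y, covariates)

    def fit_with_gwas(
        self,
        genotypes: GenotypeTable,
        gwas: GwasSummary,
        y,
        covariates: pd.DataFrame,
    ) -> "PgsThresholdSearch":
        y = np.asarray(y, dtype=float)
        n = y.size
        if len(covariates) != n or genotypes.n_participants != n:
            raise ValueError("participant count mismatch")
        cov = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        dosage, beta, p = _harmonize(genotypes.subset(), gwas)
        order = np.argsort(p, kind="stable")
        p_sorted = p[order]
        weighted = _imputed_dosage(dosage) * beta  # (n, m)
        cum_scores = np.cumsum(weighted[:, order], axis=1)  # prefix k = p<=p_sorted[k]

        # residual projector onto the covariate complement
        q, _ = np.linalg.qr(cov)
        resid = lambda v: v - q @ (q.T @ v)
        ry = resid(y - y.mean())
        ss_y = float(np.sum((y - y.mean()) ** 2))
        if ss_y <= 0:
            raise ValueError("constant phenotype")
        grid = np.arange(self.grid_step, 1.0 + self.grid_step / 2, self.grid_step)
        prefix = np.searchsorted(p_sorted, grid, side="right") - 1  # -1: none pass
        uniq_prefix = np.unique(prefix[prefix >= 0])
        if uniq_prefix.size == 0:
            raise ValueError("no SNP passes any grid threshold")
        scores_u = cum_scores[:, uniq_prefix]
        rz = resid(scores_u - scores_u.mean(axis=0))
        norms = np.linalg.norm(rz, axis=0)
        usable = norms > 1e-10
        if not usable.all():
            warnings.warn("constant score at some thresholds; skipped", RuntimeWarning)
        zu = rz / np.where(usable, norms, 1.0)

        def max_increment(r_pheno: np.ndarray) -> tuple[float, int]:
            nr = np.linalg.norm(r_pheno)
            if nr <= 0:
                return 0.0, 0
            rho2 = (zu.T @ (r_pheno / nr)) ** 2
            rho2 = np.where(usable, rho2, -np.inf)
            k = int(np.argmax(rho2))
            # increment = rho^2 * SSE_cov / SST
            return float(rho2[k] * (nr**2) / ss_y), k

        obs_inc, obs_k = max_increment(ry)

        rho2_obs = (zu.T @ (ry / np.linalg.norm(ry))) ** 2 * (
            np.linalg.norm(ry) ** 2 / ss_y
        )
        rho2_obs = np.where(usable, rho2_obs, np.nan)
        # map each grid threshold to its (unique-)prefix increment
        pos = np.searchsorted(uniq_prefix, np.clip(prefix, 0, None))
        inc_grid = np.where(prefix >= 0, rho2_obs[pos], np.nan)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best_grid_idx = int(np.nanargmax(inc_grid))
        self.thresholds_ = grid
        self.r2_increments_ = inc_grid
        self.best_threshold_ = float(grid[best_grid_idx])
        self.best_r2_increment_ = float(inc_grid[best_grid_idx])
        self.best_score_ = pd.Series(
            cum_scores[:, prefix[best_grid_idx]], index=genotypes.dosage.index, name="pgs"
        )
        del cum_scores

        if self.n_permutations > 0:
            rng = np.random.default_rng(self.random_state)
            count = 0
            for _ in range(self.n_permutations):
                yp = y[rng.permutation(n)]
                rp = resid(yp - yp.mean())
                inc, _ = max_increment(rp)
                if inc >= obs_inc - 1e-15:
                    count += 1
            self.permutation_p_ = (1 + count) / (self.n_permutations + 1)
        else:
            self.permutation_p_ = None
        return self

    def result(self) -> PgsResult:
        return PgsResult(
            thresholds=self.thresholds_,
            r2_increments=self.r2_increments_,
            best_threshold=self.best_threshold_,
            best_r2_increment=self.best_r2_increment_,
            best_score=self.best_score_,
            permutation_p=self.permutation_p_,
            n_permutations=self.n_permutations,
        )


def threshold_search(
    genotypes: GenotypeTable,
    gwas: GwasSummary,
    y,
    covariates: pd.DataFrame,
    grid_step: float = 5e-5,
    n_permutations: int = 1000,
    random_state: int | None = 0,
) -> PgsResult:
    """Functional wrapper over :class:`PgsThresholdSearch`."""
    est = PgsThresholdSearch(
        grid_step=grid_step, n_permutations=n_permutations, random_state=random_state
    )
    est.fit_with_gwas(genotypes, gwas, y, covariates)
    return est.result()
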