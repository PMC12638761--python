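"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

A cohort couples four layers with known ("truth") parameters so every
downstream stage is testable without real data:

* genetics — independent Hardy-Weinberg SNPs, a sparse-causal GWAS and the
  true polygenic score (standardized weighted allele sum over causal SNPs);
* networks — per-participant, per-band, two-session coherence-like weighted
  networks.  Either a fast logit-normal edge model (``simulate_networks_direct``)
  or band-limited oscillatory ROI time series whose inter-ROI coupling
  depends on the genetic score (``simulate_roi_timeseries``);
* mediation — designated "mediator" ROIs carry a participant latent
  ``u_r = a_effect * score + sqrt(1 - a_effect^2) * eta`` that shifts all of
  the ROI's edges, so the ROI's nodal metrics track the score with
  standardized slope ~ a_effect; g receives ``b_effect`` per mediator latent
  plus a direct genetic path calibrated so the total score-g variance equals
  ``h2_pgs``;
* cognition — 15 test scores generated from the fixed second-order factor
  structure with age/sex nuisance effects, so residualization is exercised.

Sessions share a participant's true edge structure mixed with fresh noise,
``sqrt(r) * true + sqrt(1 - r) * fresh``, giving edge test-retest
correlation ~ ``session_reliability``.

One master seed; independent child streams per component and per
participant, so identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .connectivity import DEFAULT_BANDS, BandDefinition
from .genetics import GenotypeTable, GwasSummary
from .gfactor import FactorStructure, default_structure

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "simulate_genetics",
    "simulate_covariates",
    "simulate_networks_direct",
    "simulate_roi_timeseries",
    "simulate_test_scores",
    "simulate_cfa_data",
    "simulate_cohort",
    "band_limited_noise",
]


_BAND_MAP = {b.name: b for b in DEFAULT_BANDS}

#: Standardized first-order loadings of the default battery (all in
#: [0.4, 0.8]; MWT splits its loading across working memory and verbal
#: fluency).
DEFAULT_INDICATOR_LOADINGS: dict[str, dict[str, float]] = {
    "VLMT_1_5": {"verbal_memory": 0.80},
    "VLMT_R_E": {"verbal_memory": 0.78},
    "D2_R": {"attention": 0.75},
    "Stroop_2": {"attention": 0.70},
    "Stroop_3": {"attention": 0.72},
    "TMT_A": {"attention": 0.65},
    "TMT_B": {"attention": 0.70},
    "DS_total": {"attention": 0.65},
    "LPS_3": {"attention": 0.68},
    "LPS_7": {"attention": 0.66},
    "DS_f": {"working_memory": 0.75},
    "DS_b": {"working_memory": 0.70},
    "MWT": {"working_memory": 0.50, "verbal_fluency": 0.45},
    "WF_S": {"verbal_fluency": 0.78},
    "WF_W": {"verbal_fluency": 0.74},
}

#: Standardized second-order loadings of the four factors on g.
DEFAULT_SECOND_ORDER_LOADINGS: dict[str, float] = {
    "verbal_memory": 0.88,
    "attention": 0.93,
    "working_memory": 0.88,
    "verbal_fluency": 0.84,
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults follow the study conditions the pipeline targets: 434
    participants aged 20-70, 82 cortical ROIs, five bands, two sessions
    about two hours apart, a polygenic score explaining 4% of g variance,
    and planted mediation paths a = b = 0.4 on five mediator ROIs (effect
    sizes chosen for statistical power; the reference analysis reports
    selection maps, not path magnitudes).
    """

    n_participants: int = 434
    n_snps: int = 2000
    n_causal_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_pgs: float = 0.04
    mediator_rois: tuple[int, ...] = (4, 13, 27, 55, 70)
    a_effect: float = 0.4
    b_effect: float = 0.4
    n_rois: int = 82
    bands: tuple[str, ...] = ("delta", "theta", "low_alpha", "high_alpha", "beta")
    mediator_bands: tuple[str, ...] | None = None  # None = all bands
    session_reliability: float = 0.85
    epoch_count: int = 30
    sample_rate: float = 200.0
    duration: float = 124.0  # seconds; 30 epochs of 8 s at 50% overlap
    # logit-normal edge model; the mean/sd keep weights concentrated around
    # 0.6 so the direct edge is (almost) always the shortest path and nodal
    # efficiency responds near-linearly to edge shifts
    edge_logit_mean: float = 0.4
    edge_logit_sd: float = 0.3
    mediator_edge_slope: float = 0.35
    # time-series model
    coupling_base: float = 1.0
    coupling_slope: float = 0.6
    private_amp: float = 0.9
    noise_amp: float = 0.5
    # nuisance effects on raw test scores
    score_age_effect: float = 0.3
    score_age2_effect: float = 0.1
    score_sex_effect: float = 0.2
    stratified: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.n_snps <= 0 or self.n_rois <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_causal_snps <= self.n_snps:
            raise ValueError("n_causal_snps must lie in [0, n_snps]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie inside (0, 1)")
        if not 0.0 < self.h2_pgs < 1.0:
            raise ValueError("h2_pgs must lie in (0, 1)")
        if not 0.0 < self.session_reliability <= 1.0:
            raise ValueError("session_reliability must lie in (0, 1]")
        if any(r < 0 or r >= self.n_rois for r in self.mediator_rois):
            raise ValueError("mediator_rois must lie in [0, n_rois)")
        for name in self.bands:
            band = _BAND_MAP.get(name)
            if band is None:
                raise ValueError(f"unknown band {name!r}")
            if band.f_hi >= self.sample_rate / 2:
                raise ValueError(f"band {name} above Nyquist")

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(_BAND_MAP[name] for name in self.bands)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the truth record (never read by analysis)."""

    config: CohortConfig
    covariates: pd.DataFrame  # index id: age, sex, PC1..PC4
    genotypes: GenotypeTable
    gwas: GwasSummary
    test_scores: pd.DataFrame
    true_g: np.ndarray
    networks: dict[str, np.ndarray] | None  # band -> (n, 2 sessions, R, R)
    truth: dict
    roi_timeseries: Iterator[tuple[str, np.ndarray, np.ndarray]] | None = None


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# genetics


def simulate_genetics(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, GwasSummary, np.ndarray]:
    """HWE genotypes, a sparse-effect GWAS and the true polygenic score.

    SNPs are independent; genotype frequencies are (q^2, 2pq, p^2) by
    binomial draws of two alleles.  Causal SNPs keep their true effect in
    the summary statistics with a small published p (log-uniform 1e-8 to
    1e-3); the rest carry null effects with uniform p.  The true score is
    the standardized weighted allele sum over causal SNPs (all-zero when
    there are none).  In ``stratified`` mode two subpopulations with
    diverged MAFs exercise the PC-outlier filter.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, m = config.n_participants, config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, m)
    if config.stratified:
        half = n // 2
        shift = rng.uniform(-0.15, 0.15, m)
        p_pop = np.vstack(
            [np.clip(maf - shift, 0.01, 0.99), np.clip(maf + shift, 0.01, 0.99)]
        )
        pop = np.repeat([0, 1], [half, n - half])
        dosage = rng.binomial(2, p_pop[pop])
    else:
        dosage = rng.binomial(2, maf[None, :], size=(n, m))
    snp_ids = [f"rs{i + 1}" for i in range(m)]
    participant_ids = [f"P{i + 1:04d}" for i in range(n)]
    alleles = rng.choice(["A", "C", "G", "T"], size=(m, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    geno = GenotypeTable(
        dosage=pd.DataFrame(
            dosage.astype(float), index=participant_ids, columns=snp_ids
        ),
        meta=pd.DataFrame(
            {"effect_allele": alleles[:, 0], "other_allele": alleles[:, 1]},
            index=pd.Index(snp_ids, name="snp"),
        ),
    )

    causal_idx = rng.choice(m, size=config.n_causal_snps, replace=False)
    beta = rng.normal(0.0, 0.1, m)
    p_pub = rng.uniform(0.0, 1.0, m)
    p_pub = np.clip(p_pub, 1e-300, 1.0)
    p_pub[causal_idx] = 10 ** rng.uniform(-8, -3, config.n_causal_snps)
    gwas = GwasSummary(
        pd.DataFrame(
            {
                "snp": snp_ids,
                "effect_allele": alleles[:, 0],
                "other_allele": alleles[:, 1],
                "beta": beta,
                "p": p_pub,
                "info": np.round(rng.uniform(0.92, 1.0, m), 4),
            }
        )
    )

    if config.n_causal_snps == 0:
        true_score = np.zeros(n)
    else:
        raw = dosage[:, causal_idx] @ beta[causal_idx]
        sd = raw.std(ddof=1)
        true_score = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    truth_ids = [snp_ids[i] for i in sorted(causal_idx)]
    simulate_genetics.last_causal_snps = truth_ids  # inspected by simulate_cohort
    return geno, gwas, true_score


def simulate_covariates(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Age uniform on [20, 70], sex 0/1, four standard-normal genetic PCs."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"P{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "age": rng.uniform(20.0, 70.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            **{f"PC{k}": rng.normal(0, 1, n) for k in range(1, 5)},
        },
        index=ids,
    )


# ---------------------------------------------------------------------------
# g composition


def _compose_g(
    score: np.ndarray,
    mediator_latents: np.ndarray | None,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """g = direct genetic path + b_effect per mediator latent + noise.

    The direct path is calibrated so the *total* population correlation
    between the score and g is sqrt(h2_pgs), counting both the direct and
    the mediated genetic contribution; the residual variance tops g up to
    one.
    """
    n = score.size
    s = score if score.std() > 0 else np.zeros(n)
    a, b = config.a_effect, config.b_effect
    if mediator_latents is None or mediator_latents.size == 0 or b == 0.0:
        alpha = np.sqrt(config.h2_pgs) if s.std() > 0 else 0.0
        med_term = np.zeros(n)
        var_signal = alpha**2
    else:
        r = mediator_latents.shape[1]
        cov_med = b * r * a
        var_med = b**2 * (r + r * (r - 1) * a**2)
        alpha = (np.sqrt(config.h2_pgs) - cov_med) if s.std() > 0 else 0.0
        med_term = b * mediator_latents.sum(axis=1)
        var_signal = alpha**2 + var_med + 2 * alpha * cov_med
    noise_var = 1.0 - var_signal
    if noise_var <= 0.01:
        raise ValueError(
            "planted effects leave no residual variance for g; reduce "
            "a_effect/b_effect or the number of mediator ROIs"
        )
    g = alpha * s + med_term + np.sqrt(noise_var) * rng.normal(0, 1, n)
    return g, {"direct_effect": float(alpha), "g_noise_var": float(noise_var)}


def _mediator_latents(
    score: np.ndarray, n_mediators: int, a_effect: float, rng: np.random.Generator
) -> np.ndarray:
    n = score.size
    eta = rng.normal(0, 1, (n, n_mediators))
    return a_effect * score[:, None] + np.sqrt(max(1 - a_effect**2, 0.0)) * eta


# ---------------------------------------------------------------------------
# direct network model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_networks_direct(
    config: CohortConfig,
    genetic_score: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Logit-normal edge networks with planted mediator effects (fast path).

    Edge logits are ``mean + true participant noise`` mixed across the two
    sessions with ``sqrt(r)/sqrt(1-r)`` weights; weights are the logistic
    transform, hence in (0, 1).  In each planted band, every edge incident
    to mediator ROI ``r`` is shifted by ``slope * u_r``; edges between
    non-mediator ROIs receive a small compensating shift that cancels the
    mediators' first-order leakage into non-mediator nodal sums, keeping
    non-mediator metrics uncorrelated with the score by construction.

    Returns (band -> array (n, 2, R, R), truth dict with the per-band
    mediator latents).
    """
    rng = rng or np.random.default_rng(config.seed)
    n, nroi = config.n_participants, config.n_rois
    med = np.asarray(config.mediator_rois, dtype=int)
    planted_bands = (
        set(config.mediator_bands) if config.mediator_bands is not None else set(config.bands)
    )
    rel = config.session_reliability
    iu = np.triu_indices(nroi, k=1)
    networks: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}
    nonmed = np.setdiff1d(np.arange(nroi), med)
    for band in config.bands:
        planted = band in planted_bands and med.size > 0
        u = (
            _mediator_latents(genetic_score, med.size, config.a_effect, rng)
            if med.size
            else np.zeros((n, 0))
        )
        shift = np.zeros((n, nroi, nroi))
        if planted and med.size:
            slope = config.mediator_edge_slope
            for k, r in enumerate(med):
                shift[:, r, :] += slope * u[:, k, None]
                shift[:, :, r] += slope * u[:, None, k]
            # first-order compensation on non-mediator pairs
            if nonmed.size > 1:
                total = slope * u.sum(axis=1)  # leakage into every non-mediator
                q = total / (nonmed.size - 1)
                block = np.zeros((nroi, nroi))
                block[np.ix_(nonmed, nonmed)] = 1.0
                shift -= q[:, None, None] * block[None, :, :]
        out = np.empty((n, 2, nroi, nroi))
        true_noise = rng.normal(0.0, config.edge_logit_sd, (n, iu[0].size))
        for s_idx in range(2):
            fresh = rng.normal(0.0, config.edge_logit_sd, (n, iu[0].size))
            noise = np.sqrt(rel) * true_noise + np.sqrt(1 - rel) * fresh
            z = np.zeros((n, nroi, nroi))
            z[:, iu[0], iu[1]] = config.edge_logit_mean + noise
            z[:, iu[1], iu[0]] = z[:, iu[0], iu[1]]
            z += shift
            w = _sigmoid(z)
            w = 0.5 * (w + np.transpose(w, (0, 2, 1)))
            w[:, np.arange(nroi), np.arange(nroi)] = 0.0
            out[:, s_idx] = w
        networks[band] = out
        latents[band] = u
    truth = {
        "mediator_rois": list(map(int, med)),
        "planted_bands": sorted(planted_bands),
        "latents": latents,
    }
    return networks, truth


# ---------------------------------------------------------------------------
# time-series model


def _band_limited_noise_multi(
    rng: np.random.Generator,
    n_series: int,
    n_samples: int,
    sample_rate: float,
    f_lo: float,
    f_hi: float,
) -> np.ndarray:
    """(n_series, n_samples) unit-variance noise restricted to [f_lo, f_hi] Hz."""
    white = rng.normal(0, 1, (n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    spec[:, (freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    sample_rate: float,
    f_lo: float,
    f_hi: float,
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to [f_lo, f_hi] Hz."""
    return _band_limited_noise_multi(rng, 1, n_samples, sample_rate, f_lo, f_hi)[0]


def simulate_roi_timeseries(
    config: CohortConfig,
    genetic_score: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[Iterator[tuple[str, np.ndarray, np.ndarray]], dict]:
    """Two-session band-limited oscillatory ROI signals per participant.

    Each ROI is a sum over bands of (shared source * coupling + private
    oscillator) plus white noise.  For mediator ROIs in the planted bands
    the coupling to the shared source scales linearly with the
    participant's latent ``u_r``; the participant-specific random part of
    every coupling is mixed across sessions with the
    ``sqrt(r)/sqrt(1 - r)`` weights.

    Returns (lazy iterator of (participant id, session-1 array, session-2
    array) with arrays ROI x samples, truth dict).  Lazy so an 82-ROI
    cohort never holds all signals at once.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, nroi = config.n_participants, config.n_rois
    n_samples = int(round(config.duration * config.sample_rate))
    med = np.asarray(config.mediator_rois, dtype=int)
    planted_bands = (
        set(config.mediator_bands) if config.mediator_bands is not None else set(config.bands)
    )
    rel = config.session_reliability
    bands = config.band_definitions()
    u_by_band = {
        band.name: (
            _mediator_latents(genetic_score, med.size, config.a_effect, rng)
            if med.size and band.name in planted_bands
            else np.zeros((n, med.size))
        )
        for band in bands
    }
    participant_seeds = np.random.SeedSequence(int(rng.integers(0, 2**31))).spawn(n)
    ids = [f"P{i + 1:04d}" for i in range(n)]

    freqs = np.fft.rfftfreq(n_samples, d=1.0 / config.sample_rate)
    band_bins = {
        b.name: np.flatnonzero((freqs >= b.f_lo) & (freqs <= b.f_hi)) for b in bands
    }

    def generate() -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for i, seed in enumerate(participant_seeds):
            prng = np.random.default_rng(seed)
            coupling_true = prng.normal(0.0, 0.15, (len(bands), nroi))
            sessions = []
            for s_idx in range(2):
                fresh = prng.normal(0.0, 0.15, (len(bands), nroi))
                cvar = np.sqrt(rel) * coupling_true + np.sqrt(1 - rel) * fresh
                x = config.noise_amp * prng.normal(0, 1, (nroi, n_samples))
                # private oscillators for all bands, synthesized in the
                # frequency domain with one inverse FFT per session; the
                # analytic scaling gives ~unit variance per band component
                spec = np.zeros((nroi, freqs.size), dtype=complex)
                for b_idx, band in enumerate(bands):
                    bins = band_bins[band.name]
                    scale = n_samples / np.sqrt(2.0 * bins.size)
                    z = prng.normal(0, np.sqrt(0.5), (nroi, bins.size, 2))
                    spec[:, bins] = scale * (z[..., 0] + 1j * z[..., 1])
                x += config.private_amp * np.fft.irfft(spec, n=n_samples, axis=1)
                for b_idx, band in enumerate(bands):
                    shared = band_limited_noise(
                        prng, n_samples, config.sample_rate, band.f_lo, band.f_hi
                    )
                    coup = config.coupling_base + cvar[b_idx]
                    if band.name in planted_bands and med.size:
                        coup = coup.copy()
                        coup[med] += config.coupling_slope * u_by_band[band.name][i]
                    x += coup[:, None] * shared[None, :]
                sessions.append(x)
            yield ids[i], sessions[0], sessions[1]

    truth = {
        "mediator_rois": list(map(int, med)),
        "planted_bands": sorted(planted_bands),
        "latents": u_by_band,
    }
    return generate(), truth


# ---------------------------------------------------------------------------
# cognitive scores


def _factor_model_matrices(
    structure: FactorStructure,
    indicator_loadings: dict[str, dict[str, float]],
    second_order_loadings: dict[str, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    inds = structure.indicators
    facs = structure.factor_names
    lam = np.zeros((len(inds), len(facs)))
    for ind, row in indicator_loadings.items():
        for fac, val in row.items():
            lam[inds.index(ind), facs.index(fac)] = val
    gamma = np.array([second_order_loadings[f] for f in facs])
    phi = np.outer(gamma, gamma)
    np.fill_diagonal(phi, 1.0)
    common_var = np.einsum("ij,jk,ik->i", lam, phi, lam)
    unique_var = 1.0 - common_var
    if np.any(unique_var <= 0):
        raise ValueError("loadings imply negative unique variance")
    return lam, gamma, unique_var


def simulate_cfa_data(
    n: int,
    rng: np.random.Generator,
    structure: FactorStructure | None = None,
    indicator_loadings: dict[str, dict[str, float]] | None = None,
    second_order_loadings: dict[str, float] | None = None,
    true_g: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Unit-variance indicator data drawn exactly from the second-order model.

    Returns (scores DataFrame, true g).  Useful for parameter-recovery
    checks against the CFA estimator.
    """
    structure = structure or default_structure()
    lam, gamma, unique_var = _factor_model_matrices(
        structure,
        indicator_loadings or DEFAULT_INDICATOR_LOADINGS,
        second_order_loadings or DEFAULT_SECOND_ORDER_LOADINGS,
    )
    g = true_g if true_g is not None else rng.normal(0, 1, n)
    q = gamma.size
    factors = gamma[None, :] * g[:, None] + np.sqrt(1 - gamma**2)[None, :] * rng.normal(
        0, 1, (n, q)
    )
    y = factors @ lam.T + np.sqrt(unique_var)[None, :] * rng.normal(
        0, 1, (n, lam.shape[0])
    )
    return pd.DataFrame(y, columns=structure.indicators), g


def simulate_test_scores(
    config: CohortConfig,
    true_g: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """The 15-score battery from the fixed structure plus age/sex nuisance.

    Nuisance terms (linear age, quadratic age, sex) are added on the scale
    of the standardized latent part so the residualization stage has real
    work to do.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = true_g.size
    scores, _ = simulate_cfa_data(n, rng, true_g=true_g)
    z_age = (np.asarray(age) - 45.0) / 14.4  # mean/SD of uniform [20, 70]
    z_age2 = (z_age**2 - z_age.var() - z_age.mean() ** 2)
    nuisance = (
        config.score_age_effect * z_age
        + config.score_age2_effect * z_age2
        + config.score_sex_effect * (np.asarray(sex) - 0.5)
    )
    out = scores.add(nuisance, axis=0)
    ids = [f"P{i + 1:04d}" for i in range(n)]
    out.index = ids
    return out


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(
    config: CohortConfig, networks: str = "direct"
) -> SyntheticCohort:
    """Generate a complete cohort (genetics, networks, g, battery, truth).

    ``networks='direct'`` uses the fast logit-normal edge model;
    ``networks='timeseries'`` attaches a lazy two-session ROI time-series
    iterator instead (coherence networks are then computed downstream);
    ``networks='none'`` skips networks (mediation latents still drawn so g
    has its mediated component).
    """
    rng_gen, rng_cov, rng_net, rng_g, rng_scores = _child_rngs(config.seed, 5)
    geno, gwas, score = simulate_genetics(config, rng_gen)
    causal = list(simulate_genetics.last_causal_snps)
    covars = simulate_covariates(config, rng_cov)

    nets: dict[str, np.ndarray] | None = None
    ts_iter = None
    if networks == "direct":
        nets, net_truth = simulate_networks_direct(config, score, rng_net)
    elif networks == "timeseries":
        ts_iter, net_truth = simulate_roi_timeseries(config, score, rng_net)
    elif networks == "none":
        u = (
            _mediator_latents(score, len(config.mediator_rois), config.a_effect, rng_net)
            if config.mediator_rois
            else np.zeros((config.n_participants, 0))
        )
        net_truth = {
            "mediator_rois": list(config.mediator_rois),
            "planted_bands": list(config.bands),
            "latents": {b: u for b in config.bands},
        }
    else:
        raise ValueError("networks must be 'direct', 'timeseries' or 'none'")

    # g uses the latents of one planted band (they are exchangeable draws)
    planted = net_truth["planted_bands"]
    u_for_g = net_truth["latents"][planted[0]] if planted else None
    g, g_truth = _compose_g(score, u_for_g, config, rng_g)
    scores_table = simulate_test_scores(
        config, g, covars["age"].to_numpy(), covars["sex"].to_numpy(), rng_scores
    )
    truth = {
        "causal_snps": causal,
        "true_score": score,
        "a_effect": config.a_effect,
        "b_effect": config.b_effect,
        "session_reliability": config.session_reliability,
        **net_truth,
        **g_truth,
    }
    return SyntheticCohort(
        config=config,
        covariates=covars,
        genotypes=geno,
        gwas=gwas,
        test_scores=scores_table,
        true_g=g,
        networks=nets,
        truth=truth,
        roi_timeseries=ts_iter,
    )
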