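"""General-intelligence factor (g) from a fixed second-order factor model.

The cognitive battery comprises 15 test scores that load on four correlated
first-order factors — verbal memory, attention, working memory, verbal
fluency — which in turn load on a single second-order factor g.  The
multiple-choice vocabulary test (MWT) cross-loads on working memory and
verbal fluency.  Before factoring, each score is residualized on age, sex,
age*sex, age^2 and age^2*sex by OLS and the residuals are z-standardized.

The confirmatory model is estimated by maximum likelihood on the sample
covariance S, minimizing

    F(theta) = ln|Sigma(theta)| + tr(S Sigma^-1) - ln|S| - p,

with all latent variances fixed to 1 so first- and second-order loadings are
directly standardized (second-order loadings are parameterized through tanh,
first-order factor disturbances are 1 - gamma^2).  chi2 = (n - 1) F_min;
RMSEA, SRMR, CFI and TLI follow the standard definitions against the
independence baseline.  Participant g scores use the regression (Thurstone)
method, oriented to correlate positively with the mean indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FactorStructure",
    "default_structure",
    "residualize_scores",
    "SecondOrderCFA",
    "fit_cfa",
    "fit_indices",
    "factor_scores",
]


# ---------------------------------------------------------------------------
# structure


@dataclass(frozen=True)
class FactorStructure:
    """Map first-order factors to their indicators (cross-loadings allowed)."""

    factors: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for name, inds in self.factors.items():
            if len(inds) == 0:
                raise ValueError(f"factor {name} has no indicators")

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    @property
    def indicators(self) -> list[str]:
        seen: dict[str, None] = {}
        for inds in self.factors.values():
            for ind in inds:
                seen.setdefault(ind)
        return list(seen)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def loading_pattern(self) -> np.ndarray:
        """Boolean p x q matrix of free first-order loadings."""
        inds = self.indicators
        pat = np.zeros((len(inds), self.n_factors), dtype=bool)
        for j, f in enumerate(self.factor_names):
            for ind in self.factors[f]:
                pat[inds.index(ind), j] = True
        return pat


def default_structure() -> FactorStructure:
    """The fixed 15-indicator, 4-factor battery structure.

    DS_total is modelled as its own attention indicator even though on real
    data it is the sum of the forward and backward digit spans; the
    generator draws it with its own unique part so S stays positive
    definite.
    """
    return FactorStructure(
        factors={
            "verbal_memory": ("VLMT_1_5", "VLMT_R_E"),
            "attention": (
                "D2_R",
                "Stroop_2",
                "Stroop_3",
                "TMT_A",
                "TMT_B",
                "DS_total",
                "LPS_3",
                "LPS_7",
            ),
            "working_memory": ("DS_f", "DS_b", "MWT"),
            "verbal_fluency": ("MWT", "WF_S", "WF_W"),
        }
    )


# ---------------------------------------------------------------------------
# residualization


def residualize_scores(
    scores: pd.DataFrame, age: pd.Series | np.ndarray, sex: pd.Series | np.ndarray
) -> pd.DataFrame:
    """OLS-residualize every score on age/sex terms, then z-standardize.

    Design: intercept, age, sex, age*sex, age^2, age^2*sex.  Rows with any
    missing value across scores or covariates are dropped (listwise).
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if len(age) != len(scores) or len(sex) != len(scores):
        raise ValueError("covariate length mismatch")
    complete = (
        scores.notna().all(axis=1).to_numpy() & np.isfinite(age) & np.isfinite(sex)
    )
    scores = scores.loc[complete]
    age, sex = age[complete], sex[complete]
    design = np.column_stack(
        [np.ones_like(age), age, sex, age * sex, age**2, age**2 * sex]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular covariate design (constant age or sex?)")
    y = scores.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sd = resid.std(axis=0, ddof=1)
    degenerate = sd <= 1e-12
    if np.any(degenerate):
        bad = list(scores.columns[degenerate])
        raise ValueError(f"zero residual variance for scores {bad}")
    z = (resid - resid.mean(axis=0)) / sd
    return pd.DataFrame(z, index=scores.index, columns=scores.columns)


# ---------------------------------------------------------------------------
# second-order CFA


def _implied_sigma(lam, gamma, theta_eps):
    phi = np.outer(gamma, gamma)
    np.fill_diagonal(phi, 1.0)
    return lam @ phi @ lam.T + np.diag(theta_eps), phi


class SecondOrderCFA(TransformerMixin, BaseEstimator):
    """ML second-order confirmatory factor analysis with g factor scores.

    Parameters
    ----------
    structure : FactorStructure, default the fixed battery structure.
    max_restarts : random restarts when the optimizer fails to converge.
    gtol : convergence criterion on the gradient infinity norm.
    random_state : seed for restart perturbations.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : DataFrame, standardized first-order loadings (p x q).
    second_order_loadings_ : Series, standardized loadings of the factors on g.
    unique_variances_, factor_disturbances_ : Series.
    chi2_, df_, fit_indices_ : model fit against the saturated and
        independence models.
    converged_, n_iter_, grad_norm_ : optimizer diagnostics.
    """

    def __init__(
        self,
        structure: FactorStructure | None = None,
        max_restarts: int = 5,
        gtol: float = 1e-6,
        random_state: int | None = 0,
    ):
        self.structure = structure
        self.max_restarts = max_restarts
        self.gtol = gtol
        self.random_state = random_state

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, theta, pat, q):
        n_load = int(pat.sum())
        lam = np.zeros(pat.shape)
        lam[pat] = theta[:n_load]
        if q == 1:
            gamma = np.ones(1)
            rest = theta[n_load:]
        else:
            gamma = np.tanh(theta[n_load : n_load + q])
            rest = theta[n_load + q :]
        theta_eps = np.exp(rest)
        return lam, gamma, theta_eps

    def _discrepancy(self, theta, S, logdet_S, pat, q):
        p = S.shape[0]
        lam, gamma, theta_eps = self._unpack(theta, pat, q)
        sigma, phi = _implied_sigma(lam, gamma, theta_eps)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        sigma_inv = np.linalg.inv(sigma)
        f = logdet + np.trace(S @ sigma_inv) - logdet_S - p
        # gradient: dF/dSigma = Sigma^-1 - Sigma^-1 S Sigma^-1
        a = sigma_inv - sigma_inv @ S @ sigma_inv
        grad_lam = 2.0 * (a @ lam @ phi)
        g_load = grad_lam[pat]
        if q == 1:
            g_gamma = np.empty(0)
        else:
            b = lam.T @ a @ lam
            g_raw = 2.0 * (b @ gamma) - 2.0 * gamma * np.diag(b)
            g_gamma = g_raw * (1.0 - gamma**2)  # chain through tanh
        g_eps = np.diag(a) * theta_eps  # chain through exp
        return f, np.concatenate([g_load, g_gamma, g_eps])

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y=None) -> "SecondOrderCFA":
        structure = self.structure or default_structure()
        if isinstance(X, pd.DataFrame):
            missing = [c for c in structure.indicators if c not in X.columns]
            if missing:
                raise ValueError(f"missing indicators {missing}")
            data = X[structure.indicators].to_numpy(dtype=float)
        else:
            data = np.asarray(X, dtype=float)
        n, p = data.shape
        pat = structure.loading_pattern()
        q = structure.n_factors
        n_free = int(pat.sum()) + (q if q > 1 else 0) + p
        if n <= n_free:
            raise ValueError(f"n={n} too small for {n_free} free parameters")
        S = np.cov(data, rowvar=False, ddof=1)
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance not positive definite")

        n_load = int(pat.sum())
        var = np.diag(S)
        start = np.concatenate(
            [
                np.full(n_load, 0.7) * np.sqrt(var[np.where(pat)[0]]),
                (np.full(q, np.arctanh(0.7)) if q > 1 else np.empty(0)),
                np.log(np.maximum(0.5 * var, 1e-3)),
            ]
        )
        rng = np.random.default_rng(self.random_state)
        best = None
        for attempt in range(self.max_restarts + 1):
            theta0 = start if attempt == 0 else start + rng.normal(0, 0.2, start.size)
            res = optimize.minimize(
                self._discrepancy,
                theta0,
                args=(S, logdet_S, pat, q),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 2000, "gtol": self.gtol, "ftol": 1e-14},
            )
            grad_norm = float(np.max(np.abs(res.jac)))
            if best is None or res.fun < best[0].fun:
                best = (res, grad_norm)
            if grad_norm < self.gtol * 10:
                best = (res, grad_norm)
                break
        res, grad_norm = best
        self.converged_ = bool(res.success or grad_norm < 1e-4)
        self.n_iter_ = int(res.nit)
        self.grad_norm_ = grad_norm
        if not self.converged_:
            warnings.warn(
                f"CFA optimizer did not converge (grad inf-norm {grad_norm:.2e}, "
                f"{self.n_iter_} iterations)",
                RuntimeWarning,
            )

        lam, gamma, theta_eps = self._unpack(res.x, pat, q)
        # orient factors so loadings are predominantly positive
        flip = np.sign(lam.sum(axis=0))
        flip[flip == 0] = 1.0
        lam = lam * flip
        gamma = gamma * flip
        if gamma.sum() < 0:
            gamma = -gamma
        sigma, phi = _implied_sigma(lam, gamma, theta_eps)
        # standardize loadings to the implied indicator variances
        sd = np.sqrt(np.diag(sigma))
        lam_std = lam / sd[:, None]

        inds, facs = structure.indicators, structure.factor_names
        self.structure_ = structure
        self.indicator_sd_ = pd.Series(sd, index=inds)
        self.loadings_raw_ = pd.DataFrame(lam, index=inds, columns=facs)
        self.loadings_ = pd.DataFrame(lam_std, index=inds, columns=facs)
        self.second_order_loadings_ = pd.Series(gamma, index=facs)
        self.factor_disturbances_ = pd.Series(1.0 - gamma**2, index=facs)
        self.unique_variances_ = pd.Series(theta_eps, index=inds)
        if float(theta_eps.min()) < 1e-3:
            warnings.warn(
                "near-zero unique variance (Heywood-adjacent solution): "
                f"min theta_eps = {theta_eps.min():.2e}",
                RuntimeWarning,
            )
        self.implied_cov_ = sigma
        self.factor_corr_ = phi
        self.sample_cov_ = S
        self.n_obs_ = n
        self.discrepancy_ = float(res.fun)
        self.chi2_ = (n - 1) * float(res.fun)
        self.df_ = p * (p + 1) // 2 - n_free
        self.fit_indices_ = fit_indices(self)
        self.n_features_in_ = p
        return self

    # -- scoring -------------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Regression-method (Thurstone) g scores, z-standardized."""
        return factor_scores(self, X)

    def g_scores(self, X) -> np.ndarray:
        return factor_scores(self, X)


def fit_cfa(residuals, structure: FactorStructure | None = None, **kwargs) -> SecondOrderCFA:
    """Fit the second-order CFA on residualized scores."""
    return SecondOrderCFA(structure=structure, **kwargs).fit(residuals)


def fit_indices(model: SecondOrderCFA) -> dict[str, float]:
    """chi2, df, RMSEA, SRMR, CFI, TLI for a fitted model.

    The baseline is the independence model (diagonal S).  RMSEA and TLI are
    undefined (NaN) at df = 0.
    """
    S = model.sample_cov_
    sigma = model.implied_cov_
    n = model.n_obs_
    p = S.shape[0]
    chi2, df = model.chi2_, model.df_
    sign, logdet_S = np.linalg.slogdet(S)
    f_b = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_b = (n - 1) * f_b
    df_b = p * (p - 1) // 2

    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else np.nan
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0
    if df > 0 and df_b > 0 and chi2_b / df_b != 1.0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = np.nan
    d = np.sqrt(np.diag(S))
    std_resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices(p)  # includes the diagonal
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))
    return {
        "chi2": float(chi2),
        "df": int(df),
        "rmsea": float(rmsea) if np.isfinite(rmsea) else np.nan,
        "srmr": srmr,
        "cfi": float(cfi),
        "tli": float(tli) if np.isfinite(tli) else np.nan,
    }


def factor_scores(model: SecondOrderCFA, residuals) -> np.ndarray:
    """Second-order factor scores by the regression method.

    cov(y, g) = Lambda gamma under the model, so the score weights are
    Sigma^-1 Lambda gamma.  Scores are z-standardized and oriented to
    correlate positively with the mean indicator.
    """
    structure = model.structure_
    if isinstance(residuals, pd.DataFrame):
        data = residuals[structure.indicators].to_numpy(dtype=float)
    else:
        data = np.asarray(residuals, dtype=float)
    lam = model.loadings_raw_.to_numpy()
    gamma = model.second_order_loadings_.to_numpy()
    cov_yg = lam @ gamma
    try:
        weights = np.linalg.solve(model.implied_cov_, cov_yg)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular implied covariance") from err
    centered = data - data.mean(axis=0)
    raw = centered @ weights
    sd = raw.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate factor scores (zero variance)")
    scores = raw / sd
    if np.corrcoef(scores, centered.mean(axis=1))[0, 1] < 0:
        scores = -scores
    return scores
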