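"""Mediation of the polygenic-score -> g association through network metrics.

Three layers:

* partial correlations between g, the polygenic score and global graph
  metrics, controlling for age and sex;
* single-mediator ("global") mediation: two OLS equations
  ``M ~ X + covariates`` and ``Y ~ M + X + covariates`` with the indirect
  effect a*b and its delta-method standard error (optional percentile
  bootstrap CI);
* exploratory mediation by regularization (xmed): with 82 candidate
  mediators (one nodal metric per cortical area), elastic-net models for
  path a (mediators on the score) and path b (g on all mediators) shrink
  small paths to exactly zero; mediators with |a| > 0.01, |b| > 0.01 and
  |a*b| > 0.001 on standardized variables are selected and their effects
  re-estimated without penalty, since penalized effect sizes are biased
  toward zero.

Covariates are residualized out of X, every mediator and Y before
penalization (equivalent under OLS geometry to entering them unpenalized),
and all variables are z-scored so the selection thresholds act on
standardized effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet as _SkElasticNet
from sklearn.linear_model import enet_path as _sk_enet_path
from sklearn.model_selection import KFold

__all__ = [
    "partial_correlation",
    "GlobalMediationResult",
    "global_mediation",
    "elastic_net",
    "lambda_grid",
    "PenaltyConfig",
    "MediationSelection",
    "ExploratoryMediation",
    "xmed",
    "run_band_models",
]


# ---------------------------------------------------------------------------
# partial correlation


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, controls=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing OLS control effects.

    Returns (r, two-sided p) with t-reference on n - n_controls - 2 df.
    With no controls this is the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        design = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(controls, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        design = np.column_stack([np.ones(n), c])
        k = c.shape[1]
    if n <= k + 2:
        raise ValueError("too few observations for the number of controls")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx <= 1e-12 or sy <= 1e-12:
        raise ValueError("zero residual variance")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# single-mediator mediation


@dataclass
class GlobalMediationResult:
    a: float
    b: float
    c_prime: float
    ab: float
    se_a: float
    se_b: float
    se_ab: float
    ci_ab: tuple[float, float] | None


def _ols(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and their standard errors."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    n, k = design.shape
    if n <= k:
        raise ValueError("not enough observations for OLS")
    sigma2 = resid @ resid / (n - k)
    xtx = design.T @ design
    try:
        cov = sigma2 * np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise ValueError("collinear design (covariates?)") from err
    return beta, np.sqrt(np.diag(cov))


def global_mediation(
    X,
    M,
    Y,
    covariates=None,
    n_boot: int = 0,
    random_state: int | None = 0,
) -> GlobalMediationResult:
    """Single-mediator mediation by two OLS equations.

    a from ``M ~ X + covariates``; b and the direct effect c' from
    ``Y ~ M + X + covariates``.  The indirect effect is a*b with
    delta-method SE ``sqrt(b^2 se_a^2 + a^2 se_b^2)``; with ``n_boot > 0``
    a seeded percentile bootstrap CI (95%) is added.  Significance of the
    individual paths is never a precondition for running the analysis.
    """
    x = np.asarray(X, dtype=float)
    m = np.asarray(M, dtype=float)
    y = np.asarray(Y, dtype=float)
    n = x.size
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    one = np.ones(n)

    def fit_once(x_, m_, y_, c_):
        da = np.column_stack([one[: len(x_)], x_, c_])
        beta_a, se_da = _ols(m_, da)
        db = np.column_stack([one[: len(x_)], m_, x_, c_])
        beta_b, se_db = _ols(y_, db)
        return beta_a[1], se_da[1], beta_b[1], se_db[1], beta_b[2]

    a, se_a, b, se_b, c_prime = fit_once(x, m, y, c)
    se_ab = float(np.sqrt(b**2 * se_a**2 + a**2 * se_b**2))
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(random_state)
        draws = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            ai, _, bi, _, _ = fit_once(x[idx], m[idx], y[idx], c[idx])
            draws[i] = ai * bi
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return GlobalMediationResult(
        a=float(a), b=float(b), c_prime=float(c_prime), ab=float(a * b),
        se_a=float(se_a), se_b=float(se_b), se_ab=se_ab, ci_ab=ci,
    )


# ---------------------------------------------------------------------------
# elastic net


def elastic_net(
    X, y, lam: float, alpha: float = 0.5, tol: float = 1e-7, max_iter: int = 100000
) -> np.ndarray:
    """Elastic-net coefficients minimizing
    ``(1/2n)||y - Xb||^2 + lam*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)``
    by coordinate descent.  ``lam = 0`` reduces exactly to OLS (least
    squares solve); inputs are expected pre-standardized, no intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    model = _SkElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=False, tol=tol, max_iter=max_iter
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_.copy()


def lambda_grid(
    X, y, alpha: float = 0.5, n_lambda: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all penalized coefficients
    zero) down to ``lambda_max * min_ratio``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    l1 = max(alpha, 1e-3)  # guard for pure-ridge requests
    lam_max = np.max(np.abs(X.T @ y)) / (n * l1)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _enet_single(r: np.ndarray, lam: float, alpha: float, c: float = 1.0) -> np.ndarray:
    """Closed-form single-predictor elastic net: the coordinate descent
    fixed point soft(r, lam*alpha) / (c + lam*(1-alpha)), with ``r`` the
    per-response (1/n) x'y and ``c`` the predictor scale (1/n) x'x."""
    soft = np.sign(r) * np.maximum(np.abs(r) - lam * alpha, 0.0)
    return soft / (c + lam * (1.0 - alpha))


# ---------------------------------------------------------------------------
# exploratory mediation by regularization (xmed)


@dataclass
class PenaltyConfig:
    """Elastic-net mixing (alpha), CV folds and penalty-grid settings."""

    alpha: float = 0.5
    k_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int | None = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class MediationSelection:
    """Per-mediator penalized paths, selection flags and re-estimates."""

    table: pd.DataFrame  # roi, a, b, ab, selected, a_re, b_re, ab_re, se_ab_re
    lambda_a: float
    lambda_b: float

    @property
    def selected_rois(self) -> list:
        return list(self.table.loc[self.table["selected"], "roi"])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=0, ddof=1)
    if np.any(sd <= 1e-12):
        raise ValueError("zero-variance variable after residualization")
    return (v - v.mean(axis=0)) / sd


class ExploratoryMediation(BaseEstimator):
    """xmed: elastic-net path selection of mediators with re-estimation.

    ``fit(X, M, Y, covariates)`` residualizes the covariates out of all
    variables, z-scores them, fits path a (each standardized mediator on
    the standardized score; one shared penalty chosen by pooled k-fold CV
    error across the mediator block) and path b (g on all mediators;
    penalty by k-fold CV), flags mediators passing the
    |a| > ``t_path``, |b| > ``t_path``, |a*b| > ``t_med`` thresholds, and
    re-estimates the selected paths without penalty in a joint
    multiple-mediator OLS model.

    Attributes: ``a_``, ``b_``, ``ab_``, ``selected_``, ``lambda_a_``,
    ``lambda_b_``, ``a_re_``, ``b_re_``, ``ab_re_``, ``se_ab_re_``,
    ``selection_`` (the result table).
    """

    def __init__(
        self,
        alpha: float = 0.5,
        k_folds: int = 10,
        t_med: float = 0.001,
        t_path: float = 0.01,
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-4,
        joint_reestimation: bool = True,
        random_state: int | None = 0,
    ):
        self.alpha = alpha
        self.k_folds = k_folds
        self.t_med = t_med
        self.t_path = t_path
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.joint_reestimation = joint_reestimation
        self.random_state = random_state

    def fit(self, X, M, Y, covariates=None, roi_labels=None) -> "ExploratoryMediation":
        x = np.asarray(X, dtype=float).ravel()
        m = np.asarray(M, dtype=float)
        if isinstance(M, pd.DataFrame) and roi_labels is None:
            roi_labels = list(M.columns)
        y = np.asarray(Y, dtype=float).ravel()
        n, p = m.shape
        if x.size != n or y.size != n:
            raise ValueError("X, M, Y length mismatch")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(m)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values; complete cases required")
        if n < self.k_folds:
            raise ValueError("fewer participants than CV folds")
        if covariates is None:
            design = np.ones((n, 1))
        else:
            c = np.asarray(covariates, dtype=float)
            if c.ndim == 1:
                c = c[:, None]
            design = np.column_stack([np.ones(n), c])
        x = _zscore(_residualize(x, design))
        m = _zscore(_residualize(m, design))
        y = _zscore(_residualize(y, design))

        kf = KFold(n_splits=self.k_folds, shuffle=True, random_state=self.random_state)
        folds = list(kf.split(x))

        # --- path a: mediator block on the score, shared penalty ----------
        lam_a_grid = self._shared_grid(x, m)
        cv_err = np.zeros(lam_a_grid.size)
        for train, test in folds:
            r = (x[train] @ m[train]) / train.size  # per-mediator
            c = (x[train] @ x[train]) / train.size
            for i, lam in enumerate(lam_a_grid):
                coef = _enet_single(r, lam, self.alpha, c)
                resid = m[test] - np.outer(x[test], coef)
                cv_err[i] += np.mean(resid**2)
        self.lambda_a_ = float(lam_a_grid[int(np.argmin(cv_err))])
        r_full = (x @ m) / n
        a = _enet_single(r_full, self.lambda_a_, self.alpha, (x @ x) / n)

        # --- path b: g on the full mediator block --------------------------
        lam_b_grid = lambda_grid(m, y, self.alpha, self.n_lambda, self.lambda_min_ratio)
        cv_err_b = np.zeros(lam_b_grid.size)
        for train, test in folds:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = _sk_enet_path(
                    m[train], y[train], l1_ratio=self.alpha, alphas=lam_b_grid,
                    tol=1e-7, max_iter=100000,
                )
            pred = m[test] @ coefs  # (n_test, n_lambda)
            cv_err_b += np.mean((y[test, None] - pred) ** 2, axis=0)
        self.lambda_b_ = float(lam_b_grid[int(np.argmin(cv_err_b))])
        b = elastic_net(m, y, self.lambda_b_, self.alpha)

        ab = a * b
        selected = (
            (np.abs(a) > self.t_path)
            & (np.abs(b) > self.t_path)
            & (np.abs(ab) > self.t_med)
        )

        # --- unpenalized re-estimation of the selected mediators -----------
        a_re = np.full(p, np.nan)
        b_re = np.full(p, np.nan)
        se_a_re = np.full(p, np.nan)
        se_b_re = np.full(p, np.nan)
        sel_idx = np.flatnonzero(selected)
        if sel_idx.size:
            for j in sel_idx:
                beta_j, se_j = _ols(m[:, j], np.column_stack([np.ones(n), x]))
                a_re[j], se_a_re[j] = beta_j[1], se_j[1]
            one_at_a_time = not self.joint_reestimation
            if self.joint_reestimation:
                db = np.column_stack([np.ones(n), m[:, sel_idx], x])
                try:
                    beta_b, se_db = _ols(y, db)
                except ValueError:
                    warnings.warn(
                        "collinear selected mediators; falling back to "
                        "one-at-a-time re-estimation",
                        RuntimeWarning,
                    )
                    one_at_a_time = True
                else:
                    b_re[sel_idx] = beta_b[1 : 1 + sel_idx.size]
                    se_b_re[sel_idx] = se_db[1 : 1 + sel_idx.size]
            if one_at_a_time:
                for j in sel_idx:
                    beta_j, se_j = _ols(y, np.column_stack([np.ones(n), m[:, j], x]))
                    b_re[j], se_b_re[j] = beta_j[1], se_j[1]
        ab_re = a_re * b_re
        se_ab_re = np.sqrt(b_re**2 * se_a_re**2 + a_re**2 * se_b_re**2)

        labels = roi_labels if roi_labels is not None else list(range(p))
        self.a_, self.b_, self.ab_, self.selected_ = a, b, ab, selected
        self.a_re_, self.b_re_, self.ab_re_, self.se_ab_re_ = a_re, b_re, ab_re, se_ab_re
        self.selection_ = MediationSelection(
            table=pd.DataFrame(
                {
                    "roi": labels,
                    "a": a,
                    "b": b,
                    "ab": ab,
                    "selected": selected,
                    "a_re": a_re,
                    "b_re": b_re,
                    "ab_re": ab_re,
                    "se_ab_re": se_ab_re,
                }
            ),
            lambda_a=self.lambda_a_,
            lambda_b=self.lambda_b_,
        )
        return self

    def _shared_grid(self, x: np.ndarray, m: np.ndarray) -> np.ndarray:
        """Penalty grid from the largest |(1/n) x'M_j| over the block."""
        n = x.size
        l1 = max(self.alpha, 1e-3)
        lam_max = max(np.max(np.abs(x @ m)) / (n * l1), 1e-12)
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambda)


def xmed(
    X,
    M,
    Y,
    covariates=None,
    penalty: PenaltyConfig | None = None,
    t_med: float = 0.001,
    t_path: float = 0.01,
    roi_labels=None,
) -> MediationSelection:
    """Functional wrapper over :class:`ExploratoryMediation`."""
    pen = penalty or PenaltyConfig()
    est = ExploratoryMediation(
        alpha=pen.alpha,
        k_folds=pen.k_folds,
        t_med=t_med,
        t_path=t_path,
        n_lambda=pen.n_lambda,
        lambda_min_ratio=pen.lambda_min_ratio,
        random_state=pen.seed,
    )
    est.fit(X, M, Y, covariates=covariates, roi_labels=roi_labels)
    return est.selection_


def run_band_models(
    nodal_metrics: pd.DataFrame,
    pgs: pd.Series,
    g: pd.Series,
    covariates: pd.DataFrame,
    age: pd.Series,
    age_cutoff: float = 40.0,
    bands: tuple[str, ...] = ("delta", "theta", "low_alpha", "high_alpha", "beta"),
    metrics: tuple[str, ...] = ("nodal_efficiency", "local_clustering"),
    groups: tuple[str, ...] = ("whole", "young", "older"),
    penalty: PenaltyConfig | None = None,
    t_med: float = 0.001,
    t_path: float = 0.01,
) -> dict[tuple[str, str, str], MediationSelection]:
    """One xmed model per band x nodal metric (ten in total), run for the
    whole sample and the young (age <= cutoff) / older age groups.

    ``nodal_metrics`` is the tidy table (participant, band, metric, roi,
    value); participants are aligned on the pgs index.
    """
    ids = pgs.index
    results: dict[tuple[str, str, str], MediationSelection] = {}
    member = {
        "whole": pd.Series(True, index=ids),
        "young": age.loc[ids] <= age_cutoff,
        "older": age.loc[ids] > age_cutoff,
    }
    pen = penalty or PenaltyConfig()
    for group in groups:
        sel_ids = ids[member[group]]
        if len(sel_ids) < pen.k_folds:
            raise ValueError(f"group {group!r} smaller than the CV fold count")
        for band in bands:
            for metric in metrics:
                sub = nodal_metrics[
                    (nodal_metrics["band"] == band) & (nodal_metrics["metric"] == metric)
                ]
                wide = sub.pivot(index="participant", columns="roi", values="value")
                wide = wide.loc[sel_ids]
                results[(group, band, metric)] = xmed(
                    pgs.loc[sel_ids].to_numpy(),
                    wide,
                    g.loc[sel_ids].to_numpy(),
                    covariates=covariates.loc[sel_ids].to_numpy(),
                    penalty=pen,
                    t_med=t_med,
                    t_path=t_path,
                    roi_labels=list(wide.columns),
                )
    return results
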