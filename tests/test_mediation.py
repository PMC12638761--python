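"""Partial correlations, single-mediator mediation, elastic net and xmed."""

import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import ElasticNet as SkElasticNet

import pgsmediate as pm
from pgsmediate.mediation import _enet_single, lambda_grid


class TestPartialCorrelation:
    def test_identity_gives_r_one(self, rng):
        x = rng.normal(0, 1, 100)
        c = rng.normal(0, 1, (100, 2))
        r, p = pm.partial_correlation(x, x, c)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_no_controls_reduces_to_pearson(self, rng):
        x, y = rng.normal(0, 1, (2, 200))
        r, p = pm.partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_conditionally_independent_pair_near_zero(self, rng):
        n = 10000
        z = rng.normal(0, 1, n)
        x = z + rng.normal(0, 1, n)
        y = z + rng.normal(0, 1, n)
        r_raw, _ = pm.partial_correlation(x, y)
        r_partial, _ = pm.partial_correlation(x, y, z)
        assert r_raw > 0.3  # confounded without the control
        assert abs(r_partial) < 0.05

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 150
        df = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=["x", "y", "c1", "c2"])
        ours = pm.partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert ours[0] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours[1] == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_zero_residual_variance_rejected(self, rng):
        c = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="residual variance"):
            pm.partial_correlation(2 * c, rng.normal(0, 1, 50), c)


class TestGlobalMediation:
    def test_near_deterministic_chain(self, rng):
        """X -> M -> Y with vanishing noise: a and b approach 1, so the
        indirect effect approaches 1.  (The exactly deterministic chain is
        unidentifiable: M and X become collinear in the outcome equation.)"""
        x = rng.normal(0, 1, 500)
        m = x + 1e-3 * rng.normal(0, 1, 500)
        y = m + 1e-3 * rng.normal(0, 1, 500)
        res = pm.global_mediation(x, m, y)
        assert res.a == pytest.approx(1.0, abs=1e-3)
        assert res.b == pytest.approx(1.0, abs=0.02)
        assert res.ab == pytest.approx(1.0, abs=0.02)

    def test_exactly_collinear_chain_rejected(self, rng):
        x = rng.normal(0, 1, 100)
        with pytest.raises(ValueError, match="collinear"):
            pm.global_mediation(x, x, x)

    def test_runs_without_significant_paths(self, rng):
        """The API never gates on the significance of a or b."""
        x, m, y = rng.normal(0, 1, (3, 60))
        res = pm.global_mediation(x, m, y, covariates=rng.normal(0, 1, (60, 3)))
        assert np.isfinite(res.ab) and np.isfinite(res.se_ab)

    def test_delta_ci_coverage_under_null_b(self, rng):
        """With Y independent of M given X, the true indirect effect is 0;
        the 95% delta-method interval should cover it ~95% of the time."""
        cover = 0
        n_sim = 400
        for _ in range(n_sim):
            n = 150
            x = rng.normal(0, 1, n)
            m = 0.5 * x + rng.normal(0, 1, n)
            y = 0.3 * x + rng.normal(0, 1, n)
            res = pm.global_mediation(x, m, y)
            cover += abs(res.ab) <= 1.96 * res.se_ab
        assert cover / n_sim >= 0.93

    def test_bootstrap_ci_contains_point_estimate(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        m = 0.5 * x + rng.normal(0, 1, n)
        y = 0.5 * m + rng.normal(0, 1, n)
        res = pm.global_mediation(x, m, y, n_boot=200, random_state=0)
        lo, hi = res.ci_ab
        assert lo < res.ab < hi


class TestElasticNet:
    def test_zero_penalty_reduces_to_ols(self, rng):
        X = rng.normal(0, 1, (120, 6))
        y = X @ rng.normal(0, 1, 6) + rng.normal(0, 0.2, 120)
        b = pm.elastic_net(X, y, lam=0.0)
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(b, b_ols, atol=1e-8)

    def test_lasso_matches_soft_threshold_closed_form(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        x = (x - x.mean()) / x.std()
        y = 0.6 * x + rng.normal(0, 1, n)
        y = y - y.mean()
        r = x @ y / n
        c = x @ x / n
        for lam in np.geomspace(0.001, 0.5, 12):
            fitted = pm.elastic_net(x[:, None], y, lam, alpha=1.0)[0]
            closed = _enet_single(np.array([r]), lam, 1.0, c)[0]
            assert fitted == pytest.approx(closed, abs=1e-8)

    def test_single_predictor_enet_matches_sklearn(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        y = 0.4 * x + rng.normal(0, 1, n)
        x, y = x - x.mean(), y - y.mean()
        for lam, alpha in [(0.05, 0.5), (0.2, 0.5), (0.1, 0.8)]:
            sk = SkElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False)
            sk.fit(x[:, None], y)
            closed = _enet_single(np.array([x @ y / n]), lam, alpha, x @ x / n)[0]
            assert closed == pytest.approx(sk.coef_[0], abs=1e-6)

    def test_large_penalty_zeroes_everything(self, rng):
        X = rng.normal(0, 1, (100, 5))
        y = rng.normal(0, 1, 100)
        b = pm.elastic_net(X, y, lam=1e3, alpha=0.5)
        assert np.all(b == 0.0)

    def test_lambda_grid_top_kills_all_coefficients(self, rng):
        X = rng.normal(0, 1, (150, 8))
        y = X[:, 0] * 0.5 + rng.normal(0, 1, 150)
        grid = lambda_grid(X, y, alpha=0.5)
        b = pm.elastic_net(X, y, grid[0], alpha=0.5)
        assert np.all(b == 0.0)


def planted_dataset(rng, n=300, p=30, k=3, a=0.5, b=0.5):
    x = rng.normal(0, 1, n)
    m = rng.normal(0, 1, (n, p))
    for j in range(k):
        m[:, j] = a * x + np.sqrt(1 - a**2) * rng.normal(0, 1, n)
    y = b * m[:, :k].sum(axis=1) + 0.2 * x + rng.normal(0, 1, n)
    return x, m, y, set(range(k))


class TestXmed:
    def test_planted_mediators_selected(self, rng):
        x, m, y, truth = planted_dataset(rng)
        sel = pm.xmed(x, m, y)
        chosen = set(np.flatnonzero(sel.table["selected"].to_numpy()))
        assert truth <= chosen
        assert len(chosen - truth) <= 2

    def test_reestimates_less_biased_than_penalized(self, rng):
        """Penalized paths shrink toward zero; the unpenalized re-estimates
        of truly planted mediators should sit closer to the truth."""
        bias_pen, bias_re = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x, m, y, truth = planted_dataset(r, a=0.5, b=0.5)
            est = pm.ExploratoryMediation(random_state=seed).fit(x, m, y)
            for j in truth:
                if est.selected_[j]:
                    bias_pen.append(abs(est.a_[j] - 0.5))
                    bias_re.append(abs(est.a_re_[j] - 0.5))
        assert np.mean(bias_re) < np.mean(bias_pen)

    def test_duplicated_mediator_grouping_effect(self, rng):
        """With the ridge component active (alpha = 0.5), two identical
        mediator columns receive matching nonzero path-b weights and the
        same selection flag."""
        x, m, y, _ = planted_dataset(rng, p=20, k=2)
        m[:, 10] = m[:, 0]
        y = y + 0.0
        est = pm.ExploratoryMediation(random_state=0).fit(x, m, y)
        assert est.b_[0] != 0.0 and est.b_[10] != 0.0
        assert est.b_[0] == pytest.approx(est.b_[10], abs=1e-3)
        assert est.selected_[0] == est.selected_[10]

    def test_selection_monotone_in_thresholds(self, rng):
        x, m, y, _ = planted_dataset(rng)
        loose = pm.ExploratoryMediation(t_med=0.0005, t_path=0.005, random_state=0).fit(x, m, y)
        strict = pm.ExploratoryMediation(t_med=0.01, t_path=0.05, random_state=0).fit(x, m, y)
        loose_set = set(np.flatnonzero(loose.selected_))
        strict_set = set(np.flatnonzero(strict.selected_))
        assert strict_set <= loose_set

    def test_zero_variance_mediator_rejected(self, rng):
        x = rng.normal(0, 1, 100)
        m = rng.normal(0, 1, (100, 5))
        m[:, 2] = 3.14
        with pytest.raises(ValueError, match="zero-variance"):
            pm.xmed(x, m, rng.normal(0, 1, 100))

    def test_seeded_rerun_bit_identical(self, rng):
        x, m, y, _ = planted_dataset(rng)
        s1 = pm.xmed(x, m, y, penalty=pm.PenaltyConfig(seed=11))
        s2 = pm.xmed(x, m, y, penalty=pm.PenaltyConfig(seed=11))
        assert s1.table.equals(s2.table)

    def test_permuted_outcome_selects_almost_nothing(self, rng):
        x, m, y, _ = planted_dataset(rng)
        counts = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(len(y))
            sel = pm.xmed(x, m, y[perm], penalty=pm.PenaltyConfig(seed=seed))
            counts.append(sel.n_selected)
        assert np.mean(counts) <= 2 / 30 * m.shape[1]

    def test_more_participants_than_folds_required(self, rng):
        with pytest.raises(ValueError, match="folds"):
            pm.xmed(rng.normal(0, 1, 5), rng.normal(0, 1, (5, 3)), rng.normal(0, 1, 5))


class TestRunBandModels:
    def test_band_specific_planting_is_band_specific(self):
        """Mediators planted only in theta shift only theta-band metrics, so
        selections concentrate in the theta models."""
        import pandas as pd

        from pgsmediate.networks import graph_metrics

        cfg = pm.CohortConfig(
            n_participants=250,
            n_snps=40,
            n_causal_snps=10,
            n_rois=30,
            mediator_rois=(3, 11, 22),
            a_effect=0.5,
            b_effect=0.5,
            bands=("theta", "beta"),
            mediator_bands=("theta",),
            seed=21,
        )
        cohort = pm.simulate_cohort(cfg)
        rows = []
        for band, arr in cohort.networks.items():
            mean_nets = arr.mean(axis=1)
            for i, pid in enumerate(cohort.covariates.index):
                m = graph_metrics(mean_nets[i])
                rows += [
                    (pid, band, "nodal_efficiency", r, m.E_i[r]) for r in range(30)
                ]
        tidy = pd.DataFrame(rows, columns=["participant", "band", "metric", "roi", "value"])
        ids = cohort.covariates.index
        pgs = pd.Series(cohort.truth["true_score"], index=ids)
        g = pd.Series(cohort.true_g, index=ids)
        results = pm.run_band_models(
            tidy,
            pgs,
            g,
            cohort.covariates[["age", "sex", "PC1", "PC2", "PC3", "PC4"]],
            age=cohort.covariates["age"],
            bands=("theta", "beta"),
            metrics=("nodal_efficiency",),
            groups=("whole",),
        )
        theta_sel = results[("whole", "theta", "nodal_efficiency")].n_selected
        beta_sel = results[("whole", "beta", "nodal_efficiency")].n_selected
        assert theta_sel >= 2
        assert beta_sel <= 1
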