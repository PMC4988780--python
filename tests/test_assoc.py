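"""Regression engines: OLS vs normal equations, tobit vs a grid-search
likelihood oracle, logistic closed forms, and the genome-wide scan."""

import numpy as np
import pytest
from scipy.special import log_ndtr, ndtr

from pqtlmeta import assoc, prep, simulate as sim
from pqtlmeta.assoc import logistic_fit, ols_fit, scan_analyte, tobit_fit, wald_p


class TestOls:
    def test_exact_linear_relation(self, rng):
        n = 50
        g = rng.binomial(2, 0.4, n).astype(float)
        X = np.column_stack([np.ones(n), g])
        fit = ols_fit(2.0 * g, X)
        np.testing.assert_allclose(fit.params, [0.0, 2.0], atol=1e-10)
        assert fit.scale == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        n = 6
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = ols_fit(y, X)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)  # independent closed form
        np.testing.assert_allclose(fit.params, beta_oracle, atol=1e-10)
        resid = y - X @ beta_oracle
        sigma2 = resid @ resid / (n - 3)
        se_oracle = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(fit.se, se_oracle, atol=1e-10)

    def test_permutation_invariance(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        perm = rng.permutation(n)
        a = ols_fit(y, X)
        b = ols_fit(y[perm], X[perm])
        np.testing.assert_allclose(a.params, b.params, atol=1e-12)

    def test_aliased_column_dropped_with_warning(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.warns(UserWarning, match="aliased"):
            fit = ols_fit(rng.normal(size=n), X)
        assert np.isnan(fit.params).sum() == 1

    def test_underdetermined_raises(self, rng):
        with pytest.raises(ValueError):
            ols_fit(rng.normal(size=3), rng.normal(size=(3, 4)))


def tobit_grid_oracle(y, g, c, cens, rounds=6):
    """Zooming dense grid search over (intercept, slope, sigma) for the
    censored-Gaussian likelihood; independent of the package optimizer."""
    from scipy.stats import norm

    def nll(b0, b1, s):
        xb = b0 + b1 * g
        r = (y[~cens] - xb[~cens]) / s
        val = 0.5 * np.sum(r**2) + (~cens).sum() * (np.log(s) + 0.5 * np.log(2 * np.pi))
        return val - log_ndtr((c - xb[cens]) / s).sum()

    center = np.array([0.0, 0.0, 1.0])
    width = np.array([3.0, 3.0, 2.0])
    for _ in range(rounds):
        grids = [
            np.linspace(center[0] - width[0], center[0] + width[0], 21),
            np.linspace(center[1] - width[1], center[1] + width[1], 21),
            np.linspace(max(center[2] - width[2], 0.05), center[2] + width[2], 21),
        ]
        best = None
        for b0 in grids[0]:
            for b1 in grids[1]:
                for s in grids[2]:
                    v = nll(b0, b1, s)
                    if best is None or v < best[0]:
                        best = (v, b0, b1, s)
        center = np.array(best[1:])
        width = width * 0.15
    return center


class TestTobit:
    def test_no_censoring_reduces_to_ols(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
        f_ols = ols_fit(y, X)
        f_tob = tobit_fit(y, X, y.min() - 1.0, np.zeros(n, dtype=bool))
        np.testing.assert_allclose(f_tob.params, f_ols.params, atol=1e-6)
        # the MLE sigma uses n, OLS uses n - p
        assert f_tob.scale == pytest.approx(f_ols.scale * np.sqrt((n - 2) / n), rel=1e-4)

    def test_low_censoring_stays_close_to_ols(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.4 * g + rng.normal(size=n)
        c = np.quantile(y, 0.02)
        cens = y < c
        X = np.column_stack([np.ones(n), g])
        f_ols = ols_fit(y, X)
        f_tob = tobit_fit(y, X, c - 1e-10, cens)
        assert f_tob.params[1] == pytest.approx(f_ols.params[1], abs=0.05)

    def test_matches_grid_search_oracle(self, rng):
        n = 40
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 + 0.5 * g + rng.normal(size=n)
        c = float(np.quantile(y, 0.3)) - 1e-10
        cens = y < c
        X = np.column_stack([np.ones(n), g])
        fit = tobit_fit(y, X, c, cens)
        oracle = tobit_grid_oracle(y, g, c, cens)
        assert fit.converged
        np.testing.assert_allclose(fit.params, oracle[:2], atol=1e-4)
        assert fit.scale == pytest.approx(oracle[2], abs=1e-4)

    def test_converged_fits_have_small_gradient(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        c = float(np.quantile(y, 0.3)) - 1e-10
        X = np.column_stack([np.ones(n), g])
        fit = tobit_fit(y, X, c, y < c)
        assert fit.converged
        theta = np.append(fit.params, np.log(fit.scale))
        _, grad = assoc._tobit_nll_grad(theta, y, X, c, y < c)
        assert np.linalg.norm(grad, np.inf) < 1e-6

    def test_c_above_uncensored_minimum_raises(self, rng):
        y = rng.normal(size=20)
        X = np.ones((20, 1))
        with pytest.raises(ValueError):
            tobit_fit(y, X, np.median(y), np.zeros(20, dtype=bool))


class TestLogistic:
    def test_balanced_table_no_association(self):
        # 2x2 with odds ratio 1
        x = np.repeat([0.0, 0.0, 1.0, 1.0], 10)
        y = np.tile(np.repeat([0.0, 1.0], 10), 2)
        fit = logistic_fit(y, np.column_stack([np.ones(40), x]))
        assert fit.params[1] == pytest.approx(0.0, abs=1e-8)
        assert wald_p(fit.params[1] / fit.se[1]) == pytest.approx(1.0, abs=1e-6)

    def test_two_by_two_log_odds_ratio(self):
        # exposed: 20 cases / 10 controls; unexposed: 10 cases / 20 controls
        x = np.concatenate([np.ones(30), np.zeros(30)])
        y = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
        fit = logistic_fit(y, np.column_stack([np.ones(60), x]))
        assert fit.params[1] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        fit = logistic_fit(y, np.column_stack([np.ones(20), x]))
        assert not fit.converged

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), np.ones((10, 1)))


class TestWaldIdentity:
    def test_p_equals_two_phi_of_minus_abs_z(self, rng):
        z = rng.normal(size=100) * 3
        np.testing.assert_allclose(wald_p(z), 2 * ndtr(-np.abs(z)), rtol=0, atol=0)


class TestScan:
    def _scan_setup(self, seed=21, censor=0.0, missing=0.0):
        cfg = sim.SimConfig(
            seed=seed,
            n1=400,
            n2=100,
            n_variants=30,
            missing_rate=missing,
            analytes=[
                sim.AnalyteSpec("A", causal=[("rs000007", 0.20)], censor_quantile=censor)
            ],
        )
        b1, _, _ = sim.simulate_study(cfg)
        prepared, _ = prep.prepare_panel(b1.biomarkers)
        X, _ = assoc.build_design(b1.covariates)
        return b1, prepared[0], X

    def test_planted_pqtl_attains_minimum_p(self):
        b1, pa, X = self._scan_setup()
        results = scan_analyte(pa, b1.genotypes, X, cohort="c1")
        best = min(results, key=lambda r: r.p)
        assert best.variant_id == "rs000007"
        assert best.p < 1e-10

    def test_fast_path_matches_per_variant_refit(self):
        b1, pa, X = self._scan_setup()
        results = scan_analyte(pa, b1.genotypes, X, cohort="c1")
        for j in [0, 6, 15]:  # spot-check the vectorized slopes against full refits
            g = b1.genotypes.dosage[:, j]
            fit = ols_fit(pa.y, np.column_stack([X, g]))
            r = results[j]
            assert r.beta == pytest.approx(fit.params[-1], rel=1e-10)
            assert r.se == pytest.approx(fit.se[-1], rel=1e-10)

    def test_missing_dosages_use_per_variant_complete_case(self):
        b1, pa, X = self._scan_setup(missing=0.05)
        results = scan_analyte(pa, b1.genotypes, X, cohort="c1")
        assert len(results) == b1.genotypes.n_variants
        for j, r in enumerate(results):
            g = b1.genotypes.dosage[:, j]
            rows = np.isfinite(g) & np.isfinite(pa.y)
            fit = ols_fit(pa.y[rows], np.column_stack([X[rows], g[rows]]))
            assert r.beta == pytest.approx(fit.params[-1], rel=1e-9)
            assert r.n_used == int(rows.sum())

    def test_monomorphic_variant_flagged(self):
        b1, pa, X = self._scan_setup()
        b1.genotypes.dosage[:, 3] = 2.0
        results = scan_analyte(pa, b1.genotypes, X, cohort="c1")
        r = results[3]
        assert r.flag == "monomorphic"
        assert r.beta == 0.0 and r.p == 1.0

    def test_tobit_scan_uses_censored_engine(self):
        b1, pa, X = self._scan_setup(censor=0.3)
        assert pa.mode == "tobit"
        results = scan_analyte(pa, b1.genotypes, X, cohort="c1")
        assert all(r.model == "tobit" for r in results)
        best = min(results, key=lambda r: r.p)
        assert best.variant_id == "rs000007"
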