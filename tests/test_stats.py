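"""OLS fitting, Freedman-Lane permutation tests, Cohen's d, BH-FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import dynfc
from dynfc.stats import DesignError, glm_permutation_scan


def _design(rng, n=30, p=3):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    return X


class TestFitGLM:
    def test_exact_fit_recovers_coefficients(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        y = 3.0 + 2.0 * x
        betas, _, resid = dynfc.fit_glm(y, X)
        assert np.allclose(betas, [3.0, 2.0])
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_t_statistics_match_statsmodels(self, rng):
        X = _design(rng, n=25, p=4)
        y = X @ np.array([1.0, 0.5, 0.0, -0.3]) + rng.standard_normal(25)
        betas, t_stats, _ = dynfc.fit_glm(y, X)
        fit = sm.OLS(y, X).fit()
        assert np.allclose(betas, fit.params, atol=1e-10)
        assert np.allclose(t_stats, fit.tvalues, atol=1e-10)

    def test_hand_computed_t_on_six_points(self):
        """t for the slope on a 6-point dataset, against explicit
        (X'X)^-1-based hand linear algebra."""
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.8])
        X = np.column_stack([np.ones(6), x])
        betas, t_stats, _ = dynfc.fit_glm(y, X)
        xtx_inv = np.linalg.inv(X.T @ X)
        b = xtx_inv @ X.T @ y
        resid = y - X @ b
        s2 = resid @ resid / 4
        t_hand = b[1] / np.sqrt(s2 * xtx_inv[1, 1])
        assert t_stats[1] == pytest.approx(t_hand, rel=1e-12)

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        n = 40
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        z -= z.mean()
        x -= x.mean()
        z -= (z @ x) / (x @ x) * x  # orthogonalise z against x and intercept
        y = 2.0 * x + rng.standard_normal(n)
        b1, _, _ = dynfc.fit_glm(y, np.column_stack([np.ones(n), x]))
        b2, _, _ = dynfc.fit_glm(y, np.column_stack([np.ones(n), x, z]))
        assert b2[1] == pytest.approx(b1[1], abs=1e-10)

    def test_rank_deficiency_names_collinear_term(self, rng):
        n = 20
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(DesignError, match="collinear"):
            dynfc.fit_glm(rng.standard_normal(n), X, term_names=["const", "a", "b"])


class TestPermutationTest:
    def _freedman_lane_oracle(self, y, X, term):
        """Exhaustive Freedman-Lane enumeration via per-permutation
        statsmodels OLS fits (independent of the vectorised implementation)."""
        n = len(y)
        keep = [j for j in range(X.shape[1]) if j != term]
        red = sm.OLS(y, X[:, keep]).fit()
        fitted, resid = red.fittedvalues, red.resid
        t_obs = abs(sm.OLS(y, X).fit().tvalues[term])
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            y_star = fitted + resid[list(perm)]
            t_star = abs(sm.OLS(y_star, X).fit().tvalues[term])
            count += t_star >= t_obs - 1e-12
            total += 1
        return count / total

    def test_exact_p_equals_exhaustive_enumeration(self, rng):
        n = 6
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])
        y = 0.8 * X[:, 1] + rng.standard_normal(n)
        _, _, p = dynfc.permutation_test(y, X, term=1, exact=True)
        assert p == pytest.approx(self._freedman_lane_oracle(y, X, 1), abs=1e-12)

    def test_overwhelming_effect_hits_p_floor(self, rng):
        n = 60
        x = rng.standard_normal(n)
        y = 10.0 * x + 0.01 * rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        _, _, p = dynfc.permutation_test(y, X, term=1, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_p_invariant_to_affine_rescaling(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])
        y = 0.4 * X[:, 1] + rng.standard_normal(n)
        _, _, p1 = dynfc.permutation_test(y, X, term=1, n_perm=300, seed=9)
        X2 = X.copy()
        X2[:, 1] = 5.0 * X2[:, 1] - 2.0
        _, _, p2 = dynfc.permutation_test(3.0 * y + 7.0, X2, term=1, n_perm=300, seed=9)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_seed_determinism_and_manly_mode(self, rng):
        n = 25
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        r1 = dynfc.permutation_test(y, X, term=1, n_perm=100, seed=4)
        r2 = dynfc.permutation_test(y, X, term=1, n_perm=100, seed=4)
        assert r1 == r2
        _, _, p_manly = dynfc.permutation_test(y, X, term=1, n_perm=100, seed=4, method="manly")
        assert 0 < p_manly <= 1

    def test_rejects_intercept_and_bad_nperm(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        y = rng.standard_normal(10)
        with pytest.raises(ValueError):
            dynfc.permutation_test(y, X, term=0)
        with pytest.raises(ValueError):
            dynfc.permutation_test(y, X, term=1, n_perm=0)


class TestCohensD:
    def test_unit_separation(self):
        a = np.array([0.0, 1.0, 2.0])
        d = dynfc.cohens_d(a + 1.0, a)
        assert d == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert dynfc.cohens_d(a, a) == 0.0

    def test_hand_example(self):
        assert dynfc.cohens_d(np.array([2.0, 4.0]), np.array([1.0, 3.0])) == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            dynfc.cohens_d(np.array([1.0, 1.0]), np.array([1.0, 1.0]))


class TestFDR:
    def test_step_up_hand_example(self):
        passed = dynfc.fdr_correct(np.array([0.01, 0.02, 0.04, 0.5]), alpha=0.05)
        assert list(passed) == [True, True, False, False]
        # hand check: sorted p_i vs i*alpha/m = (0.0125, 0.025, 0.0375, 0.05)
        # largest i with p_i <= i*alpha/m is i=2

    def test_all_ones_none_pass(self):
        assert not dynfc.fdr_correct(np.ones(5)).any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert dynfc.fdr_correct(np.array([0.04]), alpha=0.05)[0]
        assert not dynfc.fdr_correct(np.array([0.06]), alpha=0.05)[0]

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            dynfc.fdr_correct(np.array([]))


def test_scan_listwise_deletion_and_family(rng):
    n = 50
    table = pd.DataFrame(
        {
            "f1": rng.standard_normal(n),
            "f2": rng.standard_normal(n),
            "age": rng.standard_normal(n),
            "sex": rng.integers(0, 2, n).astype(float),
        }
    )
    table.loc[:4, "f2"] = np.nan
    res = glm_permutation_scan(
        table, responses=["f1", "f2"], covariates=["age", "sex"], term="age",
        n_perm=99, seed=0, family="demo",
    )
    assert list(res["n"]) == [50, 45]
    assert res["fdr_pass"].notna().all()
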