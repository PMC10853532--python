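"""Permutation-GLM group inference on subject-level dynamic features.

Each subject-level feature (mean synchronisation, a state's fractional
occupancy, a transition probability, ...) is the response of an ordinary
least-squares model with an intercept and the study covariates, e.g.

    y ~ 1 + PMA + PND + sex + motion_outliers

The term of interest is tested two-sidedly with a Freedman-Lane residual
permutation scheme: the reduced model (without the term) is fitted, its
residuals are permuted and added back to its fitted values, the full model
is refitted on each permuted response, and the absolute refitted
t-statistics form the null distribution.  This respects the nuisance
covariates, unlike naive response shuffling (which is also available for
comparison).  Families of p-values (one feature type across states or
transition cells) are corrected with the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "fit_glm",
    "permutation_test",
    "cohens_d",
    "fdr_correct",
    "glm_permutation_scan",
]

_EXACT_LIMIT = 9  # 9! = 362880 permutations; beyond this exact mode refuses


@dataclass
class StatResult:
    """One tested (feature, term) pair."""

    feature: str
    term: str
    beta: float
    t_statistic: float
    p_perm: float
    n: int
    n_permutations: int
    seed: int
    family: str | None = None
    fdr_pass: bool | None = None


class DesignError(ValueError):
    """Raised for rank-deficient or malformed design matrices."""


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    # QR with pivoting exposes (near-)collinear columns by tiny |R_ii|
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise DesignError(f"design matrix is rank deficient; collinear terms: {bad}")


def fit_glm(
    y: np.ndarray,
    X: np.ndarray,
    term_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary least squares with classical t-statistics.

    Parameters
    ----------
    y
        Response vector, length n, no missing values (listwise deletion is
        the caller's responsibility and is done by
        :func:`glm_permutation_scan`).
    X
        n x p design matrix including the intercept column.

    Returns
    -------
    betas, t_statistics, residuals
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise DesignError("y and X have different numbers of rows")
    if n <= p:
        raise DesignError(f"need n > p, got n={n}, p={p}")
    names = term_names or [f"x{j}" for j in range(p)]
    _check_full_rank(X, names)
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ (X.T @ y)
    residuals = y - X @ betas
    sigma2 = residuals @ residuals / (n - p)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = betas / se
    return betas, t_stats, residuals


def _t_for_term_batch(X: np.ndarray, Y: np.ndarray, j: int) -> np.ndarray:
    """t-statistic of column j for each response column of Y (n x m)."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)                    # (p, m)
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / (n - p)
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        return B[j] / se


def permutation_test(
    y: np.ndarray,
    X: np.ndarray,
    term: int,
    n_perm: int = 10000,
    seed: int = 0,
    method: str = "freedman_lane",
    exact: bool = False,
) -> tuple[float, float, float]:
    """Two-sided permutation p-value for one design column.

    Parameters
    ----------
    term
        Index of the column of interest in ``X`` (not the intercept,
        assumed to be column 0).
    method
        ``"freedman_lane"`` (default) permutes reduced-model residuals;
        ``"manly"`` permutes the raw response.
    exact
        Enumerate all n! permutations (n <= 9) and report the exact
        proportion with ``|t*| >= |t_obs|`` (the identity permutation is
        included, so p >= 1/n!).  Otherwise ``n_perm`` random permutations
        are drawn and the add-one estimate
        ``p = (1 + #{|t*| >= |t_obs|}) / (1 + n_perm)`` is returned.

    Returns
    -------
    beta, t_obs, p_perm
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if term == 0 or not (0 < term < p):
        raise ValueError(f"term must index a non-intercept column, got {term}")
    if not exact and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("freedman_lane", "manly"):
        raise ValueError(f"unknown permutation method: {method}")

    betas, t_stats, _ = fit_glm(y, X)
    t_obs = float(t_stats[term])

    if method == "freedman_lane":
        keep = [j for j in range(p) if j != term]
        Xr = X[:, keep]
        br = np.linalg.lstsq(Xr, y, rcond=None)[0]
        fitted_r = Xr @ br
        resid_r = y - fitted_r
        base, shuffled = fitted_r, resid_r
    else:  # manly: permute y itself
        base, shuffled = np.zeros_like(y), y

    if exact:
        if n > _EXACT_LIMIT:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_LIMIT}")
        perms = np.array(list(_iter_permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    Ystar = base[None, :] + shuffled[perms]    # (m, n)
    t_star = _t_for_term_batch(X, Ystar.T, term)
    exceed = np.abs(t_star) >= np.abs(t_obs) - 1e-12
    if exact:
        p_perm = float(exceed.mean())
    else:
        p_perm = float((1 + exceed.sum()) / (1 + n_perm))
    return float(betas[term]), t_obs, p_perm


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled (n_a + n_b - 2)-denominator SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def fdr_correct(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions for one family of p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value family")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, alpha=alpha, method="fdr_bh")[0]


def glm_permutation_scan(
    table: pd.DataFrame,
    responses: list[str],
    covariates: list[str],
    term: str,
    n_perm: int = 10000,
    seed: int = 0,
    family: str | None = None,
    alpha: float = 0.05,
    method: str = "freedman_lane",
) -> pd.DataFrame:
    """Test one covariate against many subject-level features.

    For every response column, subjects with a missing response or missing
    covariate are dropped (listwise deletion, n reported per row), the GLM
    is fitted with an intercept plus ``covariates``, and the permutation
    p-value for ``term`` is computed.  All responses are treated as one
    FDR family (Benjamini-Hochberg at ``alpha``) unless ``family`` is None
    and ``fdr_pass`` is left for the caller.
    """
    if term not in covariates:
        raise ValueError(f"term {term!r} must be among the covariates")
    term_idx = 1 + covariates.index(term)
    rows = []
    for i, resp in enumerate(responses):
        cols = [resp] + covariates
        sub = table[cols].dropna()
        y = sub[resp].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), sub[covariates].to_numpy(dtype=float)])
        beta, t_obs, p = permutation_test(
            y, X, term_idx, n_perm=n_perm, seed=seed + i, method=method
        )
        rows.append(
            StatResult(
                feature=resp,
                term=term,
                beta=beta,
                t_statistic=t_obs,
                p_perm=p,
                n=len(sub),
                n_permutations=n_perm,
                seed=seed + i,
                family=family,
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    if family is not None:
        out["fdr_pass"] = fdr_correct(out["p_perm"].to_numpy(), alpha=alpha)
    return out
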