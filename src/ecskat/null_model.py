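"""Null generalized linear model: trait regressed on non-genetic covariates only.

The score tests in this package need four things from the null fit: the
fitted conditional means mu0, the raw residuals r = y - mu0, the dispersion
phi0 (residual variance for Gaussian traits, 1 for Bernoulli), and the
conditional variances v_i. The variance-weighted residual projection

    P0 = V - V Xt (Xt' V Xt)^-1 Xt' V,   Xt = [1 | X],  V = diag(v)

is exposed as an operator (two small solves per application) rather than an
n x n matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import linalg

from .dataset import Dataset

__all__ = ["NullModelFit", "NullModelError", "SeparationError", "fit_null", "projection_apply", "projection_matrix"]

_DENSE_LIMIT = 2000  # dense P0 only for testing-sized problems


class NullModelError(ValueError):
    """Raised when the null model cannot be fit."""


class SeparationError(NullModelError):
    """Logistic fit did not converge (e.g. complete separation)."""


@dataclass
class NullModelFit:
    """Maximum-likelihood null fit of y on an intercept plus covariates.

    ``v`` holds the conditional variances: sigma0^2 for every sample under a
    Gaussian trait, mu0_i (1 - mu0_i) under a Bernoulli trait.
    """

    alpha0: float
    alpha: np.ndarray
    mu0: np.ndarray
    r: np.ndarray
    phi0: float
    v: np.ndarray
    trait_type: str


def _design(X: np.ndarray, n: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        X = np.empty((n, 0))
    return np.column_stack([np.ones(n), X])


def fit_null(dataset: Dataset, dispersion: str = "ml") -> NullModelFit:
    """Fit the null GLM (identity link for continuous, logit for binary traits).

    ``dispersion='ml'`` divides the Gaussian residual sum of squares by n (the
    maximum-likelihood estimate); ``'unbiased'`` divides by n - m - 1, an
    option exposed because SKAT implementations differ on this point.
    """
    y, X = dataset.y, dataset.X
    n, m = dataset.n, dataset.m
    if n <= m + 1:
        raise NullModelError(f"n={n} too small for m={m} covariates plus intercept")
    Xt = _design(X, n)
    if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
        raise NullModelError("intercept-augmented covariate matrix is rank deficient")

    if dataset.trait_type == "continuous":
        res = sm.OLS(y, Xt).fit()
        mu0 = np.asarray(res.fittedvalues)
        r = y - mu0
        denom = n if dispersion == "ml" else n - m - 1
        phi0 = float(r @ r) / denom
        if phi0 <= 0:
            raise NullModelError("zero residual variance under the null model")
        v = np.full(n, phi0)
        params = np.asarray(res.params)
    else:
        try:
            res = sm.GLM(y, Xt, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
            raise SeparationError(f"logistic null fit failed: {exc}") from exc
        if not res.converged:
            raise SeparationError("logistic null fit did not converge in 100 iterations")
        mu0 = np.asarray(res.fittedvalues)
        if np.any(mu0 <= 0) or np.any(mu0 >= 1):
            raise SeparationError("fitted probabilities hit {0,1}: separation")
        r = y - mu0
        phi0 = 1.0
        v = mu0 * (1.0 - mu0)
        params = np.asarray(res.params)

    return NullModelFit(
        alpha0=float(params[0]),
        alpha=params[1:].copy(),
        mu0=mu0,
        r=r,
        phi0=phi0,
        v=v,
        trait_type=dataset.trait_type,
    )


def projection_apply(fit: NullModelFit, X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Compute P0 @ M without materializing the n x n projection.

    Cost is O(n m k) time and O(n(m + k)) memory for an n x k input.
    """
    M = np.asarray(M, dtype=float)
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    n = fit.mu0.size
    Xt = _design(X, n)
    VM = fit.v[:, None] * M
    VXt = fit.v[:, None] * Xt
    gram = Xt.T @ VXt
    try:
        cf = linalg.cho_factor(gram)
    except linalg.LinAlgError as exc:
        raise NullModelError("singular weighted Gram matrix Xt' V Xt") from exc
    out = VM - VXt @ linalg.cho_solve(cf, Xt.T @ VM)
    return out.ravel() if squeeze else out


def projection_matrix(fit: NullModelFit, X: np.ndarray) -> np.ndarray:
    """Dense P0 for small problems (testing / cross-checking only)."""
    n = fit.mu0.size
    if n > _DENSE_LIMIT:
        raise NullModelError(f"dense P0 refused for n={n} > {_DENSE_LIMIT}")
    return projection_apply(fit, X, np.eye(n))
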