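"""Variance-component (SKAT) and burden score tests for a gene set.

Given a null-model fit, the SKAT statistic for a weighted linear kernel
K = G diag(w) G' is

    Q = r' K r / phi0 = sum_j w_j (g_j' r)^2 / phi0,

whose asymptotic null distribution is the chi-square mixture with
coefficients eig(P0^{1/2} K P0^{1/2} / phi0) — computed here via the similar
p x p matrix diag(sqrt(w)) G'P0G diag(sqrt(w)) / phi0. Burden tests collapse
the gene set into one scalar per sample and refer the squared score to
chi-square(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .dataset import Dataset
from .mixchisq import MixtureSpec, survival_info
from .null_model import NullModelFit, projection_apply

__all__ = [
    "WeightVector",
    "TestResult",
    "UntestableSetError",
    "maf_weights",
    "skat_statistic",
    "null_eigenvalues",
    "skat_test",
    "burden_aggregate",
    "burden_test",
]


class UntestableSetError(ValueError):
    """The gene set carries no testable signal (e.g. G in the null design span)."""


@dataclass
class WeightVector:
    """A point of the probability simplex over variants."""

    w: np.ndarray
    source: str = "custom"  # uniform | beta_pdf | learned | custom

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to one; use from_raw to normalize")
        self.w = w

    @classmethod
    def uniform(cls, p: int) -> "WeightVector":
        return cls(np.full(p, 1.0 / p), source="uniform")

    @classmethod
    def from_raw(cls, raw: np.ndarray, source: str = "custom") -> "WeightVector":
        raw = np.asarray(raw, dtype=float).ravel()
        total = raw.sum()
        if np.any(raw < 0) or total <= 0:
            raise ValueError("raw weights must be nonnegative with positive sum")
        return cls(raw / total, source=source)


@dataclass
class TestResult:
    Q: float
    lambdas: np.ndarray
    p_value: float
    method: str
    metadata: dict = field(default_factory=dict)


def maf_weights(G: np.ndarray, a: float = 1.0, b: float = 25.0, squared: bool = True) -> WeightVector:
    """Beta-pdf weights of the per-variant sample MAF, normalized to the simplex.

    ``squared=True`` (the original SKAT convention) squares the pdf value
    before normalization. Monomorphic variants keep the pdf value at MAF 0
    with a warning.
    """
    if a <= 0 or b <= 0:
        raise ValueError("beta parameters must be positive")
    G = np.asarray(G, dtype=float)
    maf = G.mean(axis=0) / 2.0
    if np.any(maf == 0):
        warnings.warn(f"{int((maf == 0).sum())} monomorphic variant(s); weight taken at pdf(0)")
    raw = beta_dist.pdf(maf, a, b)
    if squared:
        raw = raw**2
    return WeightVector.from_raw(raw, source="beta_pdf")


def skat_statistic(fit: NullModelFit, G: np.ndarray, w: WeightVector) -> float:
    """Q = r'Kr/phi0 computed in factored form, never materializing K."""
    t = np.asarray(G, dtype=float).T @ fit.r
    return float(np.sum(w.w * t**2) / fit.phi0)


def null_eigenvalues(fit: NullModelFit, X: np.ndarray, G: np.ndarray, w: WeightVector) -> MixtureSpec:
    """Nonzero eigenvalues of A = P0^{1/2} K P0^{1/2} / phi0.

    Computed on the p x p similar matrix diag(sqrt(w)) B diag(sqrt(w)) / phi0
    with B = G'P0G (same nonzero spectrum, cheaper for n >> p). Negatives from
    roundoff are clipped; if every eigenvalue is numerically zero the set is
    untestable.
    """
    G = np.asarray(G, dtype=float)
    B = G.T @ projection_apply(fit, X, G)
    sw = np.sqrt(w.w)
    psi = (sw[:, None] * B * sw[None, :]) / fit.phi0
    lam = np.linalg.eigvalsh(psi)
    lam = np.clip(lam, 0.0, None)
    if lam.max(initial=0.0) <= 0.0:
        raise UntestableSetError("all null eigenvalues are zero; genotypes lie in the null design span")
    return MixtureSpec(lambdas=lam[lam > 0])


def skat_test(dataset: Dataset, fit: NullModelFit, w: WeightVector) -> TestResult:
    """SKAT p-value for the weighted linear kernel given a null fit."""
    Q = skat_statistic(fit, dataset.G, w)
    spec = null_eigenvalues(fit, dataset.X, dataset.G, w)
    res = survival_info(spec, Q)
    return TestResult(
        Q=Q,
        lambdas=spec.lambdas,
        p_value=res.p,
        method=f"skat[{w.source}]",
        metadata={"pvalue_method": res.method, **res.metadata},
    )


def burden_aggregate(G: np.ndarray, agg: str = "sum") -> np.ndarray:
    """Collapse the gene set into one scalar per sample (sum or max of counts)."""
    G = np.asarray(G, dtype=float)
    if agg == "sum":
        return G.sum(axis=1)
    if agg == "max":
        return G.max(axis=1)
    raise ValueError(f"unknown aggregation {agg!r}")


def burden_test(dataset: Dataset, fit: NullModelFit, agg: str = "sum") -> TestResult:
    """GLM score test of the collapsed burden scalar, referred to chi-square(1)."""
    c = burden_aggregate(dataset.G, agg)
    if np.ptp(c) == 0:
        raise UntestableSetError("burden aggregate is constant across samples")
    P0c = projection_apply(fit, dataset.X, c)
    denom = float(c @ P0c)
    if denom <= 0:
        raise UntestableSetError("burden aggregate lies in the null design span")
    # score U = c'r/phi, efficient information c'P0c/phi^2, so U^2/I = (c'r)^2 / c'P0c
    stat = float(c @ fit.r) ** 2 / denom
    return TestResult(
        Q=stat,
        lambdas=np.empty(0),
        p_value=float(chi2.sf(stat, 1)),
        method=f"burden[{agg}]",
    )
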