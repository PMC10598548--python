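"""Tail probabilities of nonnegative mixtures of independent chi-square(1) variables.

The asymptotic null distribution of the variance-component score statistic is
T = sum_j lambda_j chi^2_1,j with nonnegative mixture coefficients lambda (the
eigenvalues of P0^{1/2} K P0^{1/2} / phi0). Two evaluators are provided:

* :func:`survival_davies` — numerically exact inversion of the characteristic
  function (Imhof's integral, evaluated with oscillatory-weight quadrature to
  a requested absolute accuracy);
* :func:`survival_liu` — the Liu–Tang–Zhang moment-matched noncentral
  chi-square approximation, which always returns a value.

:func:`survival` prefers the exact route and falls back to the approximation
when the inversion reports a fault, recording which method produced the
number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import chi2, ncx2

__all__ = [
    "MixtureSpec",
    "InversionError",
    "survival_davies",
    "survival_liu",
    "survival",
    "survival_info",
]

_RELATIVE_FLOOR = 1e-10  # eigenvalues below this fraction of max are numerical zeros


class InversionError(RuntimeError):
    """Characteristic-function inversion reported a fault."""


@dataclass
class MixtureSpec:
    """Mixture coefficients lambda >= 0, sorted descending on construction."""

    lambdas: np.ndarray
    accuracy: float = 1e-9

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float).ravel()
        if lam.size == 0 or np.any(lam < 0) or not np.any(lam > 0):
            raise ValueError("mixture coefficients must be nonnegative with at least one positive")
        self.lambdas = np.sort(lam)[::-1]
        if self.accuracy <= 0:
            raise ValueError("accuracy must be positive")

    def pruned(self) -> np.ndarray:
        """Coefficients with numerical zeros (< 1e-10 * max) dropped."""
        lam = self.lambdas
        return lam[lam > _RELATIVE_FLOOR * lam[0]]


def _imhof_integrals(lam: np.ndarray, q: float, epsabs: float):
    # Imhof:  P(T >= q) = 1/2 + (1/pi) Int_0^inf sin(theta(u)) / (u rho(u)) du
    # with theta(u) = (1/2) sum arctan(lam_j u) - q u / 2 and
    # rho(u) = prod (1 + lam_j^2 u^2)^{1/4}.  Splitting sin(phi - qu/2) into
    # cos(qu/2) and sin(qu/2) components lets QAWF handle the oscillation on
    # the infinite interval.
    def f_cos(u: float) -> float:
        if u == 0.0:
            return 0.5 * float(np.sum(lam))
        phi = 0.5 * float(np.sum(np.arctan(lam * u)))
        rho = float(np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))
        return np.sin(phi) / (u * rho)

    def f_sin(u: float) -> float:
        if u == 0.0:
            return 0.0
        phi = 0.5 * float(np.sum(np.arctan(lam * u)))
        rho = float(np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))
        return np.cos(phi) / (u * rho)

    w = q / 2.0
    i1, e1 = integrate.quad(f_cos, 0, np.inf, weight="cos", wvar=w, epsabs=epsabs, limit=10**5)
    i2, e2 = integrate.quad(f_sin, 0, np.inf, weight="sin", wvar=w, epsabs=epsabs, limit=10**5)
    return i1 - i2, e1 + e2


def survival_davies(spec: MixtureSpec, q: float) -> float:
    """Pr(sum_j lambda_j chi^2_1 >= q) by exact characteristic-function inversion.

    Raises :class:`InversionError` when the quadrature cannot certify the
    requested accuracy or the result falls outside [0, 1] by more than the
    error estimate — the caller is expected to fall back to the moment
    approximation.
    """
    if not np.isfinite(q):
        raise ValueError("q must be finite")
    if q <= 0:
        return 1.0
    lam = spec.pruned()
    try:
        integral, err = _imhof_integrals(lam, float(q), epsabs=spec.accuracy / np.pi)
    except Exception as exc:  # pragma: no cover - quadrature-internal failure
        raise InversionError(str(exc)) from exc
    p = 0.5 + integral / np.pi
    tol = max(spec.accuracy, err / np.pi)
    if err / np.pi > 100 * spec.accuracy or p < -tol or p > 1 + tol:
        raise InversionError(f"inversion fault: p={p}, error estimate {err / np.pi}")
    return float(min(max(p, 0.0), 1.0))


def survival_liu(spec: MixtureSpec, q: float) -> float:
    """Liu–Tang–Zhang moment-matched noncentral chi-square tail approximation."""
    if not np.isfinite(q):
        raise ValueError("q must be finite")
    if q <= 0:
        return 1.0
    lam = spec.pruned()
    c1, c2, c3, c4 = (float(np.sum(lam**k)) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s1**2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = dof + delta, np.sqrt(2 * (dof + 2 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    p = ncx2.sf(t, dof, delta) if delta > 0 else chi2.sf(t, dof)
    return float(min(max(p, 0.0), 1.0))


@dataclass
class SurvivalResult:
    p: float
    method: str  # 'davies' or 'liu'
    metadata: dict = field(default_factory=dict)


def survival_info(spec: MixtureSpec, q: float) -> SurvivalResult:
    """Tail probability with provenance: exact inversion, Liu on fault."""
    try:
        return SurvivalResult(p=survival_davies(spec, q), method="davies")
    except InversionError as exc:
        return SurvivalResult(p=survival_liu(spec, q), method="liu", metadata={"fault": str(exc)})


def survival(spec: MixtureSpec, q: float) -> float:
    """The p-value function p0(q) = Pr(T >= q); see :func:`survival_info`."""
    return survival_info(spec, q).p
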