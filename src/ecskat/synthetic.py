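"""Synthetic gene-set data with sparse, MAF-linked, mixed-sign genetic effects.

The generating model is a GLM with an optional pairwise-interaction term that
the fitted (linear-kernel) tests never see:

    eta_i = alpha0 + alpha' x_i + beta' g_i + g_i' Gamma g_i,

continuous traits add Gaussian noise to eta, binary traits draw Bernoulli
with logistic(eta). Minor-allele frequencies follow a truncated power law,
genotypes are Binomial(2, maf) under Hardy–Weinberg equilibrium with
independent variants, and causal effect magnitudes grow as the MAF shrinks
(|beta_j| = c |log10 maf_j| / 2) with independent random signs — the regime
in which burden collapsing cancels signal but variance-component tests do
not. Gamma is symmetric, zero on the diagonal and supported on causal pairs
only; a nonzero ``interaction_scale`` turns on the misspecification setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .dataset import Dataset

__all__ = ["SimConfig", "SimTruth", "draw_mafs", "draw_genotypes", "draw_effects", "simulate", "resample_semiempirical"]


@dataclass
class SimConfig:
    """Generator settings; defaults give the correctly specified sparse-effect study.

    ``effect_scale=None`` resolves per trait type: 0.6 for continuous, 1.0 for
    binary. ``interaction_scale=0`` is the correctly specified model; 0.3 is
    the default magnitude for the misspecified setting.
    """

    n: int = 1000
    p: int = 50
    maf_range: tuple[float, float] = (5e-4, 0.05)
    maf_exponent: float = 1.0
    causal_fraction: float = 0.1
    effect_scale: float | None = None
    mixed_signs: bool = True
    interaction_scale: float = 0.0
    trait_type: str = "continuous"
    covariate_effects: tuple[float, tuple[float, ...]] = (0.0, (0.5, 0.5))
    prevalence: float = 0.2
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low < high < 0.5")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0, 1]")

    def resolved_effect_scale(self) -> float:
        if self.effect_scale is not None:
            return self.effect_scale
        return 0.6 if self.trait_type == "continuous" else 1.0


@dataclass
class SimTruth:
    """Ground truth bundled with the generated dataset."""

    mafs: np.ndarray
    beta: np.ndarray
    causal_idx: np.ndarray
    Gamma: np.ndarray
    dataset: Dataset
    config: SimConfig = field(repr=False, default=None)


def draw_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. draws from the truncated power-law density ∝ m^(-exponent), by inverse CDF."""
    lo, hi = cfg.maf_range
    u = rng.uniform(size=cfg.p)
    g = cfg.maf_exponent
    if abs(g - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    e = 1.0 - g
    return (lo**e + u * (hi**e - lo**e)) ** (1.0 / e)


def draw_genotypes(mafs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """G_ij ~ Binomial(2, maf_j), independent variants (Hardy–Weinberg, no LD)."""
    return rng.binomial(2, np.asarray(mafs)[None, :], size=(n, len(mafs))).astype(float)


def draw_effects(mafs: np.ndarray, cfg: SimConfig, rng: np.random.Generator):
    """Sparse beta with |beta_j| = c |log10 maf_j| / 2 on causal indices, and Gamma.

    Signs are i.i.d. +-1 when ``mixed_signs`` (same-direction effects — the
    burden-friendly regime — otherwise). Gamma is symmetric with zero diagonal,
    nonzero only on causal x causal pairs, entries interaction_scale * N(0,1).
    """
    p = len(mafs)
    beta = np.zeros(p)
    Gamma = np.zeros((p, p))
    k = int(np.ceil(cfg.causal_fraction * p))
    if cfg.causal_fraction == 0 or k == 0:
        return beta, Gamma, np.empty(0, dtype=int)
    causal = np.sort(rng.choice(p, size=k, replace=False))
    mag = cfg.resolved_effect_scale() * np.abs(np.log10(mafs[causal])) / 2.0
    signs = rng.choice([-1.0, 1.0], size=k) if cfg.mixed_signs else np.ones(k)
    beta[causal] = signs * mag
    if cfg.interaction_scale != 0:
        for a_i, j in enumerate(causal):
            for kk in causal[a_i + 1 :]:
                val = cfg.interaction_scale * rng.standard_normal()
                Gamma[j, kk] = Gamma[kk, j] = val
    return beta, Gamma, causal


def _draw_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    # one Bernoulli(0.5) (e.g. sex) and one standard-normal column (e.g. age z-score)
    return np.column_stack([rng.binomial(1, 0.5, size=n).astype(float), rng.standard_normal(n)])


def simulate(cfg: SimConfig, seed: int | None = None) -> SimTruth:
    """Generate a full dataset plus ground truth from the GLM model above.

    For binary traits the intercept is solved (bisection on the sample mean of
    logistic(eta)) so the expected prevalence matches ``cfg.prevalence``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mafs = draw_mafs(cfg, rng)
    G = draw_genotypes(mafs, cfg.n, rng)
    beta, Gamma, causal = draw_effects(mafs, cfg, rng)
    X = _draw_covariates(cfg.n, rng)
    alpha0, alpha = cfg.covariate_effects
    alpha = np.asarray(alpha, dtype=float)
    eta_nogene = alpha0 + X @ alpha
    eta = eta_nogene + G @ beta
    if cfg.interaction_scale != 0:
        eta = eta + np.sum((G @ Gamma) * G, axis=1)

    if cfg.trait_type == "continuous":
        y = eta + cfg.noise_sd * rng.standard_normal(cfg.n)
    else:
        base = eta - alpha0  # re-solve the intercept for the target prevalence

        def mean_prev(a0: float) -> float:
            return float(expit(a0 + base).mean()) - cfg.prevalence

        a0 = brentq(mean_prev, -30.0, 30.0)
        probs = expit(a0 + base)
        for attempt in range(10):
            y = rng.binomial(1, probs).astype(float)
            if 0 < y.sum() < cfg.n:
                break
        else:
            raise RuntimeError("binary simulation produced a single class after 10 attempts")

    ds = Dataset(y=y, X=X, G=G, trait_type=cfg.trait_type)
    return SimTruth(mafs=mafs, beta=beta, causal_idx=causal, Gamma=Gamma, dataset=ds, config=cfg)


def resample_semiempirical(source: Dataset, n: int, seed: int | None = None) -> Dataset:
    """Draw n rows without replacement from a real dataset (semi-empirical nulls)."""
    if n > source.n:
        raise ValueError(f"cannot draw {n} samples without replacement from {source.n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(source.n, size=n, replace=False)
    return source.subset(idx)
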