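"""Learning the kernel weights on the simplex — the ecSKAT core.

For the weighted linear kernel K_w = G diag(w) G', the SKAT statistic and its
null spectrum combine into the alignment-style objective

    J(w) = Q(w) / ||lambda0(w)||_2 = w's / sqrt(w' (B ⊙ B) w),

where B = G'P0G, s = (G'r)^2 elementwise, and ⊙ is the Hadamard product.
Maximizing J over the simplex is equivalent (up to normalization, by scale
invariance of J) to the nonnegative quadratic program

    min_{z >= 0}  z'(B ⊙ B)z - 2 z'c,        c = s,

solved here exactly with an active-set NNLS reformulation. The modified
objective replaces c by s - b with b = diag(B); it centers each component
score at its null mean and yields, via sub-exponential concentration of
chi-square mixtures, the certified null p-value bound

    p0(Q(w)) <= exp(-min(Jt(w), Jt(w)^2) / 8).

The full procedure splits samples into a learning fraction and a held-out
testing fraction: weights come only from the first, the reported p-value only
from the second, which keeps the test valid despite the data-driven kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import nnls

from .association import TestResult, WeightVector, skat_test
from .dataset import Dataset
from .null_model import NullModelFit, fit_null, projection_apply

__all__ = [
    "ProjectedGram",
    "LearnedKernel",
    "projected_gram",
    "objective",
    "solve_weights",
    "pvalue_bound",
    "certified_level",
    "split_indices",
    "ecskat_test",
    "multi_kernel_stats",
]


@dataclass
class ProjectedGram:
    """Sufficient statistics for kernel learning: B = G'P0G, s = (G'r)^2, b = diag(B)."""

    B: np.ndarray
    s: np.ndarray
    b: np.ndarray
    phi0: float


@dataclass
class LearnedKernel:
    w_star: WeightVector
    J: float
    J_mod: float
    bound: float
    train_idx: np.ndarray
    test_idx: np.ndarray
    result: TestResult
    metadata: dict = field(default_factory=dict)


def projected_gram(fit: NullModelFit, X: np.ndarray, G: np.ndarray) -> ProjectedGram:
    """Compute (B, s, b) in operator form: O(np^2 + nmp) time, no n x n matrix."""
    G = np.asarray(G, dtype=float)
    PG = projection_apply(fit, X, G)
    B = G.T @ PG
    B = 0.5 * (B + B.T)  # symmetrize roundoff
    t = G.T @ fit.r
    return ProjectedGram(B=B, s=t**2, b=np.diag(B).copy(), phi0=fit.phi0)


def objective(pg: ProjectedGram, w: WeightVector, centered: bool = False) -> float:
    """J(w) = w's / sqrt(w'(B⊙B)w), or the centered Jt(w) with numerator w'(s-b)."""
    ww = w.w
    denom_sq = float(ww @ ((pg.B * pg.B) @ ww))
    if denom_sq <= 0:
        raise ValueError("objective denominator vanishes: weights supported on projected-out variants")
    num = float(ww @ (pg.s - pg.b)) if centered else float(ww @ pg.s)
    return num / np.sqrt(denom_sq)


def _qp_nonneg(M: np.ndarray, c: np.ndarray, ridge_scale: float = 1e-8):
    """Solve min_{z>=0} z'Mz - 2z'c for PSD M via an NNLS reformulation.

    With M = R'R (Cholesky) the objective equals ||Rz - d||^2 - ||d||^2 for
    R'd = c, so Lawson–Hanson NNLS returns the exact KKT point. A small ridge
    is added on the diagonal when M is numerically semidefinite.
    """
    p = M.shape[0]
    ridge_used = 0.0
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        ridge_used = ridge_scale * np.trace(M) / p
        L = np.linalg.cholesky(M + ridge_used * np.eye(p))
    d = linalg.solve_triangular(L, c, lower=True)
    z, _ = nnls(L.T, d)
    grad = 2.0 * ((M + ridge_used * np.eye(p)) @ z - c)
    active = z <= 0
    kkt = max(
        float(np.max(np.abs(grad[~active]), initial=0.0)),
        float(np.max(-grad[active], initial=0.0)),
    )
    return z, {"kkt_residual": kkt, "ridge": ridge_used}


def solve_weights(pg: ProjectedGram, centered: bool = False, return_info: bool = False):
    """Maximize J (or the centered Jt) over the simplex via the nonnegative QP.

    Returns uniform weights flagged ``no_signal`` when the QP minimizer is the
    origin (the linear term has no positive part — nothing to learn).
    """
    M = pg.B * pg.B
    c = pg.s - pg.b if centered else pg.s
    z, info = _qp_nonneg(M, c)
    if z.sum() <= 0:
        w = WeightVector.uniform(pg.s.size)
        info["no_signal"] = True
    else:
        w = WeightVector.from_raw(z, source="learned")
        info["no_signal"] = False
    return (w, info) if return_info else w


def pvalue_bound(J_mod: float) -> float:
    """exp(-min(J, J^2)/8), the certified upper bound on the null p-value.

    Nonpositive modified objectives give the vacuous bound 1.
    """
    if not np.isfinite(J_mod):
        raise ValueError("J_mod must be finite")
    if J_mod <= 0:
        return 1.0
    return float(min(1.0, np.exp(-min(J_mod, J_mod**2) / 8.0)))


def certified_level(J_mod: float) -> float:
    """Largest a >= 0 with 10^-a >= the bound: a = min(J, J^2)/(8 ln 10)."""
    if not np.isfinite(J_mod):
        raise ValueError("J_mod must be finite")
    if J_mod <= 0:
        return 0.0
    return float(min(J_mod, J_mod**2) / (8.0 * np.log(10.0)))


def split_indices(dataset: Dataset, train_ratio: float, rng: np.random.Generator):
    """Random learn/test partition; stratified by class for binary traits."""
    if not 0.0 < train_ratio < 1.0:
        raise ValueError("train_ratio must be in (0, 1)")
    n = dataset.n
    if dataset.trait_type == "binary":
        train_parts = []
        for cls in (0.0, 1.0):
            idx = np.flatnonzero(dataset.y == cls)
            idx = rng.permutation(idx)
            k = int(round(train_ratio * idx.size))
            train_parts.append(idx[:k])
        train = np.sort(np.concatenate(train_parts))
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[: int(round(train_ratio * n))])
    mask = np.zeros(n, dtype=bool)
    mask[train] = True
    test = np.flatnonzero(~mask)
    return train, test


def ecskat_test(
    dataset: Dataset,
    train_ratio: float = 0.3,
    seed: int | None = None,
    centered: bool = False,
    rng: np.random.Generator | None = None,
) -> LearnedKernel:
    """Split, learn kernel weights on the learning split, test on the held-out split.

    The null model is refit independently on each split; the reported p-value
    uses only held-out samples, so validity does not depend on how aggressively
    the weights adapt to the learning split. ``centered`` switches the learning
    objective to the modified (bound-linked) form; the bound itself is always
    computed from the learning split's centered objective at the learned w.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    train_idx, test_idx = split_indices(dataset, train_ratio, rng)
    min_n = dataset.m + 2
    if train_idx.size < min_n or test_idx.size < min_n:
        raise ValueError(
            f"split too small (train {train_idx.size}, test {test_idx.size}; need >= {min_n})"
        )
    ds_tr = dataset.subset(train_idx)
    ds_ts = dataset.subset(test_idx)

    fit_tr = fit_null(ds_tr)
    pg = projected_gram(fit_tr, ds_tr.X, ds_tr.G)
    w_star, info = solve_weights(pg, centered=centered, return_info=True)
    J = objective(pg, w_star, centered=False)
    J_mod = objective(pg, w_star, centered=True)
    bound = pvalue_bound(J_mod)

    fit_ts = fit_null(ds_ts)
    result = skat_test(ds_ts, fit_ts, w_star)
    result.method = "ecskat"
    return LearnedKernel(
        w_star=w_star,
        J=J,
        J_mod=J_mod,
        bound=bound,
        train_idx=train_idx,
        test_idx=test_idx,
        result=result,
        metadata=info,
    )


def _check_psd(K: np.ndarray, jitter: float = 1e-10) -> None:
    scale = max(float(np.trace(K)) / K.shape[0], 1.0)
    try:
        np.linalg.cholesky(K + jitter * scale * np.eye(K.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError("base kernel is not positive semi-definite") from exc


def multi_kernel_stats(fit: NullModelFit, X: np.ndarray, base_kernels, as_features: bool = False):
    """Sufficient statistics (s_L, M) for learning over arbitrary base kernels.

    For kernels K_l: s_l = r'K_l r and M_lm = tr(P0 K_l P0 K_m). With
    per-variant rank-one kernels g_j g_j' this reduces to (s, B ⊙ B).
    ``as_features=True`` interprets each entry as an n x d feature matrix F_l
    with K_l = F_l F_l' (cheaper and PSD by construction).
    """
    r = fit.r
    L = len(base_kernels)
    s_L = np.empty(L)
    if as_features:
        PF = []
        for l, F in enumerate(base_kernels):
            F = np.asarray(F, dtype=float)
            if F.ndim == 1:
                F = F[:, None]
            t = F.T @ r
            s_L[l] = float(t @ t)
            PF.append((F, projection_apply(fit, X, F)))
        M = np.empty((L, L))
        for l in range(L):
            Fl, _ = PF[l]
            for mth in range(l, L):
                _, PFm = PF[mth]
                C = Fl.T @ PFm
                M[l, mth] = M[mth, l] = float(np.sum(C * C))
    else:
        PK = []
        for l, K in enumerate(base_kernels):
            K = np.asarray(K, dtype=float)
            _check_psd(K)
            s_L[l] = float(r @ K @ r)
            PK.append(projection_apply(fit, X, K))
        M = np.empty((L, L))
        for l in range(L):
            for mth in range(l, L):
                M[l, mth] = M[mth, l] = float(np.sum(PK[l] * PK[mth].T))
    return s_L, M
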