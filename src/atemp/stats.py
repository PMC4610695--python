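"""Score statistic for multi-phenotype association and its Kendall-tau form.

The central quantity is the score test of a proportional-odds regression of
the genotype (minor-allele count 0/1/2) on K phenotypes — the "reversed
regression" used by MultiPhen.  Writing pi_k for the sample proportion of
genotype class k, the statistic is

    S = W^T V^{-1} W / (n (1-pi0)(1-pi1)(1-pi2)),

where W = sum_i gbar_i Y_i with per-individual genotype weights

    gbar_i = 1-pi0  (G_i = 0),   pi2-pi0  (G_i = 1),   pi2-1  (G_i = 2),

and V = n^{-1} sum_i (Y_i - Ybar)(Y_i - Ybar)^T.  Under the null S follows a
chi-square distribution with K degrees of freedom.

The same number arises as a generalized Kendall's tau statistic: the
U-statistic over all sample pairs with a sign kernel on genotype differences
and an identity kernel on phenotype differences is proportional to W, and
its estimated variance conditional on the phenotypes is
(1-pi0)(1-pi1)(1-pi2) * sum_i (Y_i-Ybar)(Y_i-Ybar)^T.  Both routes are
implemented here and agree to floating-point accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "genotype_freqs",
    "genotype_weights",
    "score_statistic",
    "kendall_tau_statistic",
    "batch_score_statistics",
    "permutation_pvalue",
]

#: condition number of V above which a warning is emitted
COND_WARN_THRESHOLD = 1e10


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single-variant multi-phenotype association test.

    Attributes
    ----------
    statistic : float
        Nonnegative chi-square score statistic.
    df : int
        Degrees of freedom, equal to the number of phenotypes K.
    p_asymptotic : float
        Upper-tail chi-square(df) probability at ``statistic``.
    p_permutation : float or None
        Permutation p-value ``(1 + #{S_perm >= S_obs}) / (1 + B)`` if a
        permutation test was run, else None.
    method : str
        One of ``multiphen``, ``atemp-rn``, ``atemp-or`` (which transform, if
        any, was applied to the phenotypes before testing).
    n_used : int
        Number of individuals entering the computation.
    """

    statistic: float
    df: int
    p_asymptotic: float
    p_permutation: Optional[float] = None
    method: str = "multiphen"
    n_used: int = 0


def _as_genotype_array(g) -> np.ndarray:
    g = np.asarray(g)
    if g.ndim != 1:
        raise ValueError("genotype vector must be one-dimensional")
    if g.size < 2:
        raise ValueError("need at least two individuals")
    if not np.isin(g, (0, 1, 2)).all():
        bad = np.unique(g[~np.isin(g, (0, 1, 2))])
        raise ValueError(f"genotype values must be 0, 1 or 2; found {bad}")
    return g.astype(np.int64, copy=False)


def _as_phenotype_matrix(y, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.ndim != 2:
        raise ValueError("phenotype matrix must be n x K")
    if y.shape[0] != n:
        raise ValueError(
            f"phenotype rows ({y.shape[0]}) do not match genotype length ({n})"
        )
    if not np.isfinite(y).all():
        raise ValueError("phenotype matrix contains NaN or infinite values; "
                         "drop or impute missing data before testing")
    if np.any(np.ptp(y, axis=0) == 0):
        const = np.nonzero(np.ptp(y, axis=0) == 0)[0]
        raise ValueError(f"phenotype column(s) {const.tolist()} are constant; "
                         "the phenotype covariance V would be singular")
    return y


def genotype_freqs(g, variant: str = "variant") -> tuple[float, float, float]:
    """Sample proportions (pi0, pi1, pi2) of the three genotype classes.

    Raises
    ------
    ValueError
        If only a single genotype class is present (the statistic is then
        undefined), naming ``variant`` in the message.
    """
    g = _as_genotype_array(g)
    n = g.size
    pi0 = float(np.count_nonzero(g == 0)) / n
    pi1 = float(np.count_nonzero(g == 1)) / n
    pi2 = float(np.count_nonzero(g == 2)) / n
    if max(pi0, pi1, pi2) == 1.0:
        raise ValueError(
            f"{variant}: all individuals share one genotype class; "
            "the association statistic is undefined for a monomorphic variant"
        )
    return pi0, pi1, pi2


def genotype_weights(g, variant: str = "variant") -> np.ndarray:
    """Per-individual genotype weights gbar.

    gbar_i is the average of the sign kernel between individual i's genotype
    and every other genotype, which reduces to 1-pi0, pi2-pi0 or pi2-1
    according as G_i is 0, 1 or 2.  The weights always sum to zero.
    """
    g = _as_genotype_array(g)
    pi0, pi1, pi2 = genotype_freqs(g, variant=variant)
    lookup = np.array([1.0 - pi0, pi2 - pi0, pi2 - 1.0])
    return lookup[g]


def _quadratic_form(w: np.ndarray, v: np.ndarray) -> float:
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > 1e15:
        raise np.linalg.LinAlgError(
            "phenotype covariance V is singular or numerically singular; "
            "remove collinear phenotype columns before testing"
        )
    if cond > COND_WARN_THRESHOLD:
        warnings.warn(
            f"phenotype covariance V is ill-conditioned (cond={cond:.2e}); "
            "results may be unstable", RuntimeWarning, stacklevel=3,
        )
    return float(w @ np.linalg.solve(v, w))


def score_statistic(y, g, method: str = "multiphen") -> TestResult:
    """Proportional-odds score statistic S for K phenotypes vs one variant.

    Parameters
    ----------
    y : array-like, shape (n, K) or (n,)
        Phenotype values (already transformed/residualized if desired).
    g : array-like of {0, 1, 2}, shape (n,)
        Minor-allele counts.
    method : str
        Label recorded in the result (the statistic itself is agnostic).

    Returns
    -------
    TestResult
        With asymptotic chi-square(K) p-value.
    """
    g = _as_genotype_array(g)
    n = g.size
    y = _as_phenotype_matrix(y, n)
    pi0, pi1, pi2 = genotype_freqs(g)

    # W from the genotype-class group sums
    w = ((1.0 - pi0) * y[g == 0].sum(axis=0)
         + (pi2 - pi0) * y[g == 1].sum(axis=0)
         + (pi2 - 1.0) * y[g == 2].sum(axis=0))
    yc = y - y.mean(axis=0)
    v = (yc.T @ yc) / n
    denom = n * (1.0 - pi0) * (1.0 - pi1) * (1.0 - pi2)
    stat = _quadratic_form(w, v) / denom
    k = y.shape[1]
    return TestResult(
        statistic=stat,
        df=k,
        p_asymptotic=float(sps.chi2.sf(stat, k)),
        method=method,
        n_used=n,
    )


def kendall_tau_statistic(y, g, method: str = "multiphen") -> TestResult:
    """Generalized Kendall's tau statistic S2 (sign kernel on genotype).

    Computes U = sum_i gbar_i Y_i from the per-individual weights and
    normalizes by the conditional variance estimate
    (1-pi0)(1-pi1)(1-pi2) * sum_i (Y_i-Ybar)(Y_i-Ybar)^T.  Numerically equal
    to :func:`score_statistic` on any input; kept as an independent route.
    """
    g = _as_genotype_array(g)
    n = g.size
    y = _as_phenotype_matrix(y, n)
    pi0, pi1, pi2 = genotype_freqs(g)
    gbar = genotype_weights(g)

    u = gbar @ y
    yc = y - y.mean(axis=0)
    var_u = (1.0 - pi0) * (1.0 - pi1) * (1.0 - pi2) * (yc.T @ yc)
    stat = _quadratic_form(u, var_u)
    k = y.shape[1]
    return TestResult(
        statistic=stat,
        df=k,
        p_asymptotic=float(sps.chi2.sf(stat, k)),
        method=method,
        n_used=n,
    )


def batch_score_statistics(y, g) -> np.ndarray:
    """Vectorized score statistics over a batch of datasets.

    Parameters
    ----------
    y : ndarray, shape (R, n, K)
        Phenotypes for R independent datasets.
    g : ndarray, shape (R, n)
        Genotypes (0/1/2) for the same datasets.

    Returns
    -------
    ndarray, shape (R,)
        The statistic for every dataset.

    Raises
    ------
    ValueError
        If any dataset has a single genotype class or a singular V.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    if y.ndim != 3 or g.ndim != 2 or y.shape[:2] != g.shape:
        raise ValueError("expected y of shape (R, n, K) and g of shape (R, n)")
    r, n, k = y.shape

    pi = np.stack([(g == c).sum(axis=1) for c in (0, 1, 2)], axis=1) / n
    if np.any(pi.max(axis=1) == 1.0):
        bad = int(np.count_nonzero(pi.max(axis=1) == 1.0))
        raise ValueError(f"{bad} dataset(s) have a monomorphic genotype")

    # gbar per individual: index the per-replicate lookup rows by genotype
    lookup = np.stack([1.0 - pi[:, 0], pi[:, 2] - pi[:, 0], pi[:, 2] - 1.0],
                      axis=1)  # (R, 3)
    gbar = np.take_along_axis(lookup, g, axis=1)  # (R, n)

    yc = y - y.mean(axis=1, keepdims=True)
    w = np.einsum("rn,rnk->rk", gbar, yc)
    v = np.einsum("rni,rnj->rij", yc, yc) / n
    try:
        sol = np.linalg.solve(v, w[..., None])[..., 0]
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular phenotype covariance in at least one dataset; "
            "remove collinear or constant phenotype columns"
        ) from None
    quad = np.einsum("rk,rk->r", w, sol)
    denom = n * (1.0 - pi[:, 0]) * (1.0 - pi[:, 1]) * (1.0 - pi[:, 2])
    return quad / denom


def permutation_pvalue(y, g, n_permutations: int = 1000, seed: int = 0,
                       method: str = "multiphen") -> TestResult:
    """Permutation test: shuffle genotype labels, recompute the statistic.

    The p-value uses the standard add-one counting rule
    ``(1 + #{S_perm >= S_obs}) / (1 + B)`` so it is never exactly zero.
    Deterministic for a fixed ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    g = _as_genotype_array(g)
    n = g.size
    y = _as_phenotype_matrix(y, n)
    observed = score_statistic(y, g, method=method)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=g.dtype)
    for b in range(n_permutations):
        perms[b] = rng.permutation(g)
    y_batch = np.broadcast_to(y, (n_permutations, n, y.shape[1]))
    perm_stats = batch_score_statistics(y_batch, perms)

    exceed = int(np.count_nonzero(perm_stats >= observed.statistic))
    p_perm = (1.0 + exceed) / (1.0 + n_permutations)
    return TestResult(
        statistic=observed.statistic,
        df=observed.df,
        p_asymptotic=observed.p_asymptotic,
        p_permutation=p_perm,
        method=method,
        n_used=n,
    )
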