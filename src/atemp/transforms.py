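"""Phenotype transformations applied column-wise before the score test.

Two rank-based transforms restore power when phenotypes are non-normal:

* ``atemp-rn`` — rank-based inverse normal transform,
  ``Y* = Phi^{-1}(R / (n+1))`` with mid-ranks R for ties;
* ``atemp-or`` — ordinal residual transform,
  ``Y*_i = sum_j sign(Y_i - Y_j)``, the residual of an intercept-only
  proportional-odds model for an ordinal response.

``multiphen`` leaves the phenotypes untouched.  Both transforms depend on
the data only through ranks, so they are invariant under strictly monotone
distortions of each phenotype column.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "METHODS",
    "rank_inverse_normal",
    "ordinal_residual",
    "apply_method",
    "apply_method_batch",
    "residualize",
]

METHODS = ("multiphen", "atemp-rn", "atemp-or")


def _as_column(y_col) -> np.ndarray:
    y = np.asarray(y_col, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a one-dimensional phenotype column")
    if y.size < 2:
        raise ValueError("need at least two observations")
    return y


def rank_inverse_normal(y_col) -> np.ndarray:
    """Rank-based inverse normal transform Phi^{-1}(R_i / (n+1)).

    Ties receive mid-ranks before the normal quantile is applied.  The
    output is monotone in the input and, without ties, symmetric about 0.

    Raises
    ------
    ValueError
        For a constant column (ranks carry no information and the
        transformed column would be constant).
    """
    y = _as_column(y_col)
    if np.ptp(y) == 0:
        raise ValueError("constant column: rank-inverse-normal is undefined")
    ranks = rankdata(y)
    return norm.ppf(ranks / (y.size + 1))


def ordinal_residual(y_col) -> np.ndarray:
    """Ordinal residual transform Y*_i = sum_j sign(Y_i - Y_j), sign(0)=0.

    Computed through the mid-rank identity ``Y*_i = 2 R_i - (n+1)``, which
    holds exactly with ties: if c_i values are strictly below Y_i and e_i
    equal it (self included), the sign sum is 2 c_i + e_i - n while the
    mid-rank is c_i + (e_i+1)/2.  Outputs always sum to zero; a constant
    column maps to all zeros.
    """
    y = _as_column(y_col)
    return 2.0 * rankdata(y) - (y.size + 1)


def apply_method(y, method: str) -> np.ndarray:
    """Apply a named transform to every column of an n x K phenotype matrix.

    ``multiphen`` is the identity; ``atemp-rn`` and ``atemp-or`` apply
    :func:`rank_inverse_normal` / :func:`ordinal_residual` per column.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if method == "multiphen":
        out = y.copy()
    elif method == "atemp-rn":
        out = np.column_stack([rank_inverse_normal(y[:, k])
                               for k in range(y.shape[1])])
    else:
        out = np.column_stack([ordinal_residual(y[:, k])
                               for k in range(y.shape[1])])
    return out[:, 0] if squeeze else out


def apply_method_batch(y, method: str) -> np.ndarray:
    """Transform a batch of datasets at once.

    Parameters
    ----------
    y : ndarray, shape (R, n, K)
        R independent phenotype matrices; ranks are taken along axis 1.
    method : str
        One of ``multiphen``, ``atemp-rn``, ``atemp-or``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a batch of shape (R, n, K)")
    if method == "multiphen":
        return y
    n = y.shape[1]
    ranks = rankdata(y, axis=1)
    if method == "atemp-rn":
        return norm.ppf(ranks / (n + 1))
    return 2.0 * ranks - (n + 1)


def residualize(y, covariates) -> np.ndarray:
    """Replace each phenotype column by its least-squares residual on
    covariates (an intercept is always included).

    Used to adjust for covariates such as age and sex before any transform
    or test; with the genotype on the response side of the reversed
    regression, covariate adjustment happens on the phenotype side.
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("covariate rows do not match phenotype rows")
    design = np.column_stack([np.ones(x.shape[0]), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return resid[:, 0] if squeeze else resid
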