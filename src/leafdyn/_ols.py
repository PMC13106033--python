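"""Vectorised gene-wise ordinary least squares with Wald t inference.

One design matrix, thousands of response vectors.  Used by both the
leaf-age + drought model and the time + dose model.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["CovariateError", "genewise_ols"]


class CovariateError(ValueError):
    """A model covariate is constant (or the design is rank deficient)."""


def genewise_ols(X: np.ndarray, Y: np.ndarray, names: list):
    """Fit ``Y[:, g] ~ X`` for every gene column ``g``.

    Parameters
    ----------
    X
        ``n x p`` design matrix whose first column is the intercept.
    Y
        ``n x G`` response matrix (one gene per column).
    names
        Covariate names (length ``p``), used in error messages.

    Returns
    -------
    dict with ``coef`` (p x G), ``se``, ``t``, ``p`` arrays and ``df_resid``.
    Zero-variance genes get coefficient 0 and p = 1 for every non-intercept
    term.  Two-sided p-values come from the t distribution with the residual
    degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    for j in range(1, p):
        if np.ptp(X[:, j]) == 0:
            raise CovariateError(f"covariate {names[j]!r} is constant across samples")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise CovariateError(f"design with covariates {names} is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coef
    df = n - p
    if df < 1:
        raise CovariateError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    flat = Y.std(axis=0) == 0
    if flat.any():
        coef[1:, flat] = 0.0
        t[1:, flat] = 0.0
        pvals[:, flat] = 1.0
        se[:, flat] = np.nan
    return {"coef": coef, "se": se, "t": t, "p": pvals, "df_resid": df}
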