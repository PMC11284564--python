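"""Vectorized per-variant association scans and small statistical helpers.

The logistic scan is a hand-vectorized Newton (IRLS) solver for the
two-parameter model ``logit P(y=1) = a + b x`` fitted independently for every
variant column.  Fitting all variants simultaneously avoids the per-model
overhead of a generic GLM fitter and is validated against ``statsmodels``'
``Logit`` in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["logistic_scan", "ols_scan", "pearson_corr_pvalue"]


def logistic_scan(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regression of a binary outcome on each variant.

    Parameters
    ----------
    X : (n, m) dosage matrix.
    y : (n,) binary 0/1 outcome.

    Returns
    -------
    beta, se, pvalue : (m,) arrays.  Monomorphic columns (zero variance) and
    non-converged fits yield NaN; Wald p-values are two-sided normal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError("phenotype length does not match genotype rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic_scan requires a binary 0/1 phenotype")

    poly = X.std(axis=0) > 0
    a = np.full(m, special.logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    b = np.zeros(m)
    active = poly.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = a[None, :] + X * b[None, :]
        mu = special.expit(eta)
        s = mu * (1.0 - mu)
        r = y[:, None] - mu
        g1 = r.sum(axis=0)
        g2 = (X * r).sum(axis=0)
        h11 = s.sum(axis=0)
        h12 = (s * X).sum(axis=0)
        h22 = (s * X * X).sum(axis=0)
        det = h11 * h22 - h12 * h12
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        da = np.where(active, np.nan_to_num(da), 0.0)
        db = np.where(active, np.nan_to_num(db), 0.0)
        # damp huge steps (quasi-separation) to keep the iteration stable
        step = np.maximum(np.abs(da), np.abs(db))
        scale = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-300), 1.0)
        a = a + da * scale
        b = b + db * scale
        active = active & (np.maximum(np.abs(da), np.abs(db)) > tol)

    eta = a[None, :] + X * b[None, :]
    s = special.expit(eta) * (1.0 - special.expit(eta))
    h11 = s.sum(axis=0)
    h12 = (s * X).sum(axis=0)
    h22 = (s * X * X).sum(axis=0)
    det = h11 * h22 - h12 * h12
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = h11 / det
    se = np.sqrt(np.where(var_b > 0, var_b, np.nan))
    beta = b.copy()
    bad = ~poly | ~np.isfinite(se) | (np.abs(beta) > 25)
    beta[bad] = np.nan
    se[bad] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval[bad] = np.nan
    return beta, se, pval


def ols_scan(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression (with intercept) of y on each variant.

    Returns marginal slopes, their standard errors, and two-sided t-test
    p-values (df = n - 2).  Monomorphic columns yield NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    sxy = (xc * yc[:, None]).sum(axis=0)
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    bad = ~(sxx > 0)
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad | (se == 0), np.where(se == 0, 0.0, np.nan), se)
    se = np.where(bad, np.nan, se)
    pval = np.where(bad, np.nan, pval)
    return beta, se, pval


def pearson_corr_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-distribution test.

    Degenerate inputs (constant vectors, n < 3) return (0.0, 1.0) so callers
    can uniformly treat "no predictive model" as non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    if not np.isfinite(r):
        return 0.0, 1.0
    return float(r), float(p)
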