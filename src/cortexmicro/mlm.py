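"""Two-level random-intercept regression of MD on T1.

Observations are (participant, ROI) pairs: 76 regional values nested in
participants, with participant as the cluster.  The model is

    y_ij = b0 + b1 * x_ij + u_i + e_ij,
    u_i ~ N(0, var_intercept),  e_ij ~ N(0, var_residual),

a fixed slope with a random intercept per participant.  Both variables are
grand-standardized (z-scored across all observations) before fitting, so the
slope is a standardized estimate.  Estimation is full maximum likelihood via
a bounded one-dimensional profile over the variance ratio
lambda = var_intercept / var_residual: for fixed lambda the GLS fixed
effects and the residual variance have closed forms, so only lambda is
optimized numerically.  Inference on the slope is a Wald z-test using the
GLS information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["MlmFit", "standardize", "fit_random_intercept", "icc", "loglik_at"]

_LOG2PI = np.log(2 * np.pi)


@dataclass
class MlmFit:
    slope_std: float
    se: float
    p: float
    intercept: float
    var_intercept: float
    var_residual: float
    loglik: float
    n_clusters: int
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "estimate": self.slope_std, "se": self.se, "p": self.p,
            "var_intercept": self.var_intercept,
            "var_residual": self.var_residual,
            "icc": icc(self), "loglik": self.loglik,
            "n_clusters": self.n_clusters, "n_obs": self.n_obs,
        }


def standardize(df: pd.DataFrame, cols=("t1", "md")) -> pd.DataFrame:
    """Grand z-score (across all observations, all clusters) per column."""
    out = df.copy()
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {c!r} has zero variance")
        out[c] = (x - x.mean()) / sd
    return out


def _cluster_blocks(df, cluster, x, y):
    """Per-cluster sufficient statistics for the GLS profile."""
    blocks = []
    for _, sub in df.groupby(cluster, sort=False):
        xv = sub[x].to_numpy(dtype=float)
        yv = sub[y].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(xv), xv])
        blocks.append((X, yv, X.T @ X, X.sum(axis=0), X.T @ yv, yv.sum(), len(xv)))
    return blocks


def _profile(blocks, lam):
    """GLS beta, profiled sigma^2_e and -2 loglik at a given variance ratio."""
    p = 2
    A = np.zeros((p, p))
    b = np.zeros(p)
    n_total = 0
    logdet = 0.0
    for X, yv, XtX, Xs, Xty, ys, n in blocks:
        shrink = lam / (1 + n * lam)
        A += XtX - shrink * np.outer(Xs, Xs)
        b += Xty - shrink * Xs * ys
        n_total += n
        logdet += np.log1p(n * lam)
    beta = np.linalg.solve(A, b)
    rss = 0.0
    for X, yv, *_rest, n in blocks:
        r = yv - X @ beta
        rs = r.sum()
        rss += r @ r - (lam / (1 + n * lam)) * rs * rs
    sigma2 = rss / n_total
    neg2ll = n_total * (_LOG2PI + np.log(sigma2) + 1.0) + logdet
    return beta, sigma2, A, neg2ll, n_total


def fit_random_intercept(
    df: pd.DataFrame,
    cluster: str = "id",
    x: str = "t1",
    y: str = "md",
    reml: bool = False,
    max_ratio: float = 1e3,
) -> MlmFit:
    """ML fit of the fixed-slope, random-intercept model.

    Deterministic given the data.  The variance-ratio profile is maximized
    on [0, ``max_ratio``]; a boundary solution var_intercept = 0 (the model
    collapsing to pooled OLS) is permitted.  ``reml=True`` applies the REML
    adjustment to the profiled objective.
    """
    counts = df.groupby(cluster).size()
    if len(counts) < 2:
        raise ValueError("need at least 2 clusters")
    blocks = _cluster_blocks(df, cluster, x, y)
    n_total = sum(bl[-1] for bl in blocks)
    p = 2

    def objective(lam):
        beta, sigma2, A, neg2ll, _ = _profile(blocks, lam)
        if reml:
            # REML: add log|X' V^-1 X| and profile sigma^2 on n - p df
            rss = sigma2 * n_total
            sigma2_r = rss / (n_total - p)
            neg2ll = (
                (n_total - p) * (_LOG2PI + np.log(sigma2_r) + 1.0)
                + sum(np.log1p(bl[-1] * lam) for bl in blocks)
                + np.linalg.slogdet(A)[1]
            )
        return neg2ll

    # optimize on log(1+lambda) for better conditioning near the boundary
    res = minimize_scalar(
        lambda t: objective(np.expm1(t)),
        bounds=(0.0, np.log1p(max_ratio)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.expm1(res.x))
    if objective(0.0) <= res.fun:  # boundary check: var_intercept = 0
        lam = 0.0
    beta, sigma2, A, neg2ll, _ = _profile(blocks, lam)
    if reml:
        sigma2 = sigma2 * n_total / (n_total - p)
    cov_beta = sigma2 * np.linalg.inv(A)
    se = float(np.sqrt(cov_beta[1, 1]))
    from scipy.stats import norm

    z = beta[1] / se
    return MlmFit(
        slope_std=float(beta[1]),
        se=se,
        p=float(2 * norm.sf(abs(z))),
        intercept=float(beta[0]),
        var_intercept=lam * sigma2,
        var_residual=sigma2,
        loglik=-0.5 * objective(lam),
        n_clusters=len(counts),
        n_obs=n_total,
    )


def loglik_at(
    df: pd.DataFrame,
    var_intercept: float,
    var_residual: float,
    cluster: str = "id",
    x: str = "t1",
    y: str = "md",
) -> float:
    """Full ML log-likelihood at given variance components (beta profiled out).

    Used to verify that the fitted components sit at the profile optimum.
    """
    if var_residual <= 0:
        raise ValueError("var_residual must be positive")
    lam = var_intercept / var_residual
    blocks = _cluster_blocks(df, cluster, x, y)
    beta, *_ = _profile(blocks, lam)
    ll = 0.0
    for X, yv, *_rest, n in blocks:
        r = yv - X @ beta
        rs = r.sum()
        quad = (r @ r - (lam / (1 + n * lam)) * rs * rs) / var_residual
        ll += -0.5 * (
            n * _LOG2PI + n * np.log(var_residual) + np.log1p(n * lam) + quad
        )
    return float(ll)


def icc(fit: MlmFit) -> float:
    """Intraclass correlation: between-cluster share of total variance."""
    total = fit.var_intercept + fit.var_residual
    if total == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return fit.var_intercept / total
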