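"""Signal preprocessing: quantile normalization, covariate correction, binarization.

The correction step fits, for every genomic bin, a log-link Poisson
mean model of the read count across tracks on standardized covariates
(quasi-Poisson point estimates coincide with Poisson estimating
equations, so only the mean model is needed to remove covariate
effects).  The corrected value keeps the intercept scale and divides
out the covariate multiplicative term.  Binarization thresholds each
track at the smallest count whose Poisson upper-tail probability, at
the track's genome-wide mean, drops to ``pthresh``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BinaryCallMatrix, BinnedTrackMatrix

__all__ = [
    "quantile_normalize",
    "standardize_covariates",
    "regress_covariates",
    "poisson_threshold",
    "binarize",
]

IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8


def _qnorm_columns(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns so each matches the mean order-statistic curve.

    Ties within a column receive the mean of their tied quantile targets.
    """
    n, d = values.shape
    if d < 2:
        raise ValueError("need >= 2 tracks in a normalization group")
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    target = sorted_vals.mean(axis=1)  # mean of order statistics
    out = np.empty_like(values, dtype=float)
    for j in range(d):
        col = np.empty(n)
        col[order[:, j]] = target
        # average targets over ties
        uniq, inv = np.unique(values[:, j], return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=col, minlength=len(uniq))
            cnts = np.bincount(inv, minlength=len(uniq))
            col = (sums / cnts)[inv]
        out[:, j] = col
    return out


def quantile_normalize(counts: BinnedTrackMatrix, group_by_mark: bool = True) -> BinnedTrackMatrix:
    """Quantile-normalize tracks so each track's distribution across bins
    equals the mean value of the quantile within its group.

    With ``group_by_mark`` (the default) normalization runs separately
    per mark, since marks differ in genome-wide prevalence.
    """
    values = counts.values.copy()
    if group_by_mark:
        groups = counts.mark_groups().values()
    else:
        groups = [np.arange(values.shape[1])]
    for cols in groups:
        if len(cols) == 0:
            raise ValueError("empty normalization group")
        values[:, cols] = _qnorm_columns(values[:, cols])
    return BinnedTrackMatrix(values, counts.bins.copy(), counts.tracks.copy())


def standardize_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Mean-0, sd-1 scaling of every numeric covariate column."""
    num = cov.select_dtypes(include=[np.number])
    if num.isna().any().any():
        raise ValueError("covariates must have no missing values")
    sd = num.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant covariate column(s): {bad}")
    out = cov.copy()
    out[num.columns] = (num - num.mean()) / sd
    return out


def _poisson_irls(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched per-bin Poisson IRLS.

    Y: bins x tracks counts; X: tracks x (1+p) design (intercept first).
    Returns (beta bins x (1+p), converged bool per bin).  Bins whose fit
    does not converge are flagged; all-zero bins converge trivially to
    an intercept of -inf and are handled by the caller.
    """
    n_bins, n_tracks = Y.shape
    p1 = X.shape[1]
    beta = np.zeros((n_bins, p1))
    mean_y = Y.mean(axis=1)
    nonzero = mean_y > 0
    beta[:, 0] = np.where(nonzero, np.log(np.maximum(mean_y, 1e-300)), 0.0)
    active = nonzero.copy()
    converged = ~nonzero  # all-zero bins need no fit
    dev_old = np.full(n_bins, np.inf)
    for _ in range(IRLS_MAX_ITER):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        eta = beta[idx] @ X.T
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        # deviance 2*sum[y log(y/mu) - (y - mu)]
        y = Y[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev = 2.0 * (ylogy - (y - mu)).sum(axis=1)
        done = np.abs(dev - dev_old[idx]) <= IRLS_TOL * (np.abs(dev) + 0.1)
        dev_old[idx] = dev
        if done.any():
            converged[idx[done]] = True
            active[idx[done]] = False
            idx = idx[~done]
            if len(idx) == 0:
                continue
            mu = mu[~done]
            y = y[~done]
        # Newton step: (X' W X) d = X'(y - mu), W = diag(mu)
        XtWX = np.einsum("dp,bd,dq->bpq", X, mu, X)
        grad = (y - mu) @ X
        try:
            step = np.linalg.solve(XtWX, grad[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular covariate design") from exc
        beta[idx] += step
    return beta, converged


def regress_covariates(
    norm: BinnedTrackMatrix,
    cov: pd.DataFrame,
    group_by_mark: bool = True,
) -> BinnedTrackMatrix:
    """Remove multiplicative covariate effects from every bin.

    Per bin a Poisson log-link model mu_d = exp(b0 + sum_j b_j x_dj) is
    fit across the tracks of each mark; the corrected value is
    observed * exp(b0) / mu_d, i.e. the covariate term is divided out
    while the intercept scale is retained.  Bins that fail to converge
    are passed through unchanged with a warning.
    """
    cov_num = cov.select_dtypes(include=[np.number])
    cov_std = standardize_covariates(cov_num) if len(cov_num.columns) else cov_num
    Xfull = cov_std.to_numpy(dtype=float)
    if Xfull.shape[0] != len(norm.tracks):
        raise ValueError("covariate table must have one row per track")
    p = Xfull.shape[1]
    if p == 0:
        return BinnedTrackMatrix(norm.values.copy(), norm.bins.copy(), norm.tracks.copy())

    values = norm.values
    out = values.copy()
    groups = norm.mark_groups().values() if group_by_mark else [np.arange(values.shape[1])]
    n_failed = 0
    for cols in groups:
        if len(cols) < p + 2:
            raise ValueError("need at least p+2 tracks per bin to fit p covariates")
        X = np.column_stack([np.ones(len(cols)), Xfull[cols]])
        Y = values[:, cols]
        beta, converged = _poisson_irls(Y, X)
        adj = np.exp(np.clip(-(beta[:, 1:] @ Xfull[cols].T), -30, 30))  # exp(b0)/mu = exp(-x'b)
        corrected = Y * adj
        all_zero = Y.sum(axis=1) == 0
        corrected[all_zero] = 0.0
        bad = ~converged & ~all_zero
        if bad.any():
            n_failed += int(bad.sum())
            corrected[bad] = Y[bad]
        out[:, cols] = corrected
    if n_failed:
        warnings.warn(
            f"covariate fit did not converge for {n_failed} bin-group(s); "
            "observed values retained there",
            stacklevel=2,
        )
    return BinnedTrackMatrix(out, norm.bins.copy(), norm.tracks.copy())


def poisson_threshold(lam: float, pthresh: float = 1e-4) -> int:
    """Smallest integer c (>= 1) with P(X >= c) <= pthresh for X ~ Poisson(lam)."""
    if lam <= 0:
        return 1
    # P(X >= c) = sf(c - 1); ppf gives a fast starting point
    c = int(stats.poisson.ppf(1.0 - pthresh, lam))
    c = max(c, 0)
    while stats.poisson.sf(c - 1, lam) > pthresh:
        c += 1
    while c > 1 and stats.poisson.sf(c - 2, lam) <= pthresh:
        c -= 1
    return max(c, 1)


def binarize(corrected: BinnedTrackMatrix, pthresh: float = 1e-4) -> BinaryCallMatrix:
    """Presence calls from a Poisson background model.

    Per track, lambda is the mean corrected signal over all bins and the
    call threshold is the smallest integer count whose upper-tail
    probability under Poisson(lambda) is at most ``pthresh`` (at least 1).
    A bin is called present iff its value >= threshold.
    """
    if not (0 < pthresh <= 1):
        raise ValueError("pthresh must lie in (0, 1]")
    values = corrected.values
    lam = values.mean(axis=0)
    if np.any(lam == 0):
        warnings.warn("track(s) with zero mean signal: all calls 0", stacklevel=2)
    thresholds = np.array([poisson_threshold(l, pthresh) for l in lam])
    calls = (values >= thresholds[None, :]).astype(np.uint8)
    calls[:, lam == 0] = 0
    return BinaryCallMatrix(calls, corrected.bins.copy(), corrected.tracks.copy())
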