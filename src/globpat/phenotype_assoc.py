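"""Case/control association of global patterns.

Each state's per-individual emission parameters are compared between
groups with a two-sided Mann-Whitney U test; family-wise error over
states is controlled with a min-p permutation test (label shuffling).
A covariate-adjusted logistic regression provides a confirmatory check
on states of interest.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GlobalPatternModel

__all__ = [
    "mwu_phenotype",
    "permutation_adjust",
    "logistic_covariate_check",
]


def _align_labels(model: GlobalPatternModel, mark: Optional[str], labels: pd.Series):
    if mark is None:
        marks = model.marks
        if len(marks) != 1:
            raise ValueError("specify mark for a multi-mark model")
        mark = marks[0]
    block, individuals = model.mark_block(mark)
    lab = labels.reindex(individuals)
    if lab.isna().any():
        raise ValueError("labels missing for some individuals")
    lab = lab.to_numpy().astype(int)
    if lab.min() == lab.max():
        raise ValueError("both label groups must be nonempty")
    return block, lab


def _mwu_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Valid with ties; feasible for small samples only.
    """
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    mu = nx * (len(y)) / 2.0
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    d_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for comb in combinations(range(n), nx):
        u = ranks[list(comb)].sum() - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            extreme += 1
    return extreme / total


def _mwu_asymptotic(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized normal-approximation MWU with tie correction.

    values: k x n (one row per state); labels: binary per individual.
    Returns (U for group 1, two-sided p).  All-tied rows give p = 1.
    """
    k, n = values.shape
    n1 = int(labels.sum())
    n2 = n - n1
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, labels == 1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per row
    tie_term = np.zeros(k)
    for i in range(k):
        _, cnt = np.unique(values[i], return_counts=True)
        tie_term[i] = (cnt**3 - cnt).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu) / np.sqrt(var)
    p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return u1, np.minimum(p, 1.0)


def mwu_phenotype(
    model: GlobalPatternModel,
    labels: pd.Series,
    mark: Optional[str] = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of each state's emissions between groups.

    Uses exact enumeration when either group has fewer than 8
    individuals (and the total is small enough to enumerate), otherwise
    the normal approximation with tie correction.
    """
    block, lab = _align_labels(model, mark, labels)
    n1 = int(lab.sum())
    n2 = len(lab) - n1
    u, p_asym = _mwu_asymptotic(block, lab)
    use_exact = min(n1, n2) < 8 and len(lab) <= 14
    if use_exact:
        p = np.array(
            [_mwu_exact_p(row[lab == 1], row[lab == 0]) for row in block]
        )
    else:
        p = p_asym
    return pd.DataFrame({"state": np.arange(1, model.k + 1), "U": u, "p": p})


def permutation_adjust(
    model: GlobalPatternModel,
    labels: pd.Series,
    mark: Optional[str] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Min-p permutation family-wise correction across states.

    Sample labels are shuffled ``n_perm`` times; each permutation
    retains the minimum p over states.  adjusted p(state) =
    #{null min-p < observed p(state)} / n_perm (strict "more
    significant"), with a +1-smoothed variant reported alongside to
    avoid a misleading exact zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    block, lab = _align_labels(model, mark, labels)
    obs = mwu_phenotype(model, labels, mark)
    rng = np.random.default_rng(seed)
    n = len(lab)
    # ranks are label-independent: precompute once per state
    ranks = stats.rankdata(block, axis=1)
    n1 = int(lab.sum())
    n2 = n - n1
    mu = n1 * n2 / 2.0
    tie_term = np.array([(np.unique(row, return_counts=True)[1] ** 3
                          - np.unique(row, return_counts=True)[1]).sum() for row in block])
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    member = (lab[perm_idx] == 1)  # n_perm x n boolean
    r1 = member.astype(float) @ ranks.T  # n_perm x k
    u1 = r1 - n1 * (n1 + 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu) / sd[None, :]
    p_perm = np.where(var[None, :] > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    null_min = p_perm.min(axis=1)
    obs_p = obs["p"].to_numpy()
    counts = (null_min[:, None] < obs_p[None, :]).sum(axis=0)
    out = obs.copy()
    out["p_adj"] = counts / n_perm
    out["p_adj_smoothed"] = (counts + 1) / (n_perm + 1)
    out["significant"] = out["p_adj"] < 0.05
    return out


def logistic_covariate_check(
    state_emissions: np.ndarray,
    labels: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> dict:
    """Logistic regression of case status on a state's emissions plus
    covariates; Wald z-test on the emission coefficient.

    Perfect separation or non-convergence is reported via the
    ``converged`` flag with no p-value.
    """
    emissions = np.asarray(state_emissions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if emissions.std() == 0:
        raise ValueError("zero-variance emissions: design is rank deficient")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    X = emissions[:, None]
    if covariates is not None:
        X = np.column_stack([X, covariates])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(labels, X).fit(disp=False, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        return {"coef": np.nan, "z": np.nan, "p": None, "converged": False}
    if not converged or not np.isfinite(res.bse[1]) or res.bse[1] > 1e6:
        return {"coef": float(res.params[1]), "z": np.nan, "p": None, "converged": False}
    return {
        "coef": float(res.params[1]),
        "z": float(res.tvalues[1]),
        "p": float(res.pvalues[1]),
        "converged": True,
    }
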