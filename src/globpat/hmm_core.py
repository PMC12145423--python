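"""Stacked multivariate-Bernoulli hidden Markov model.

Each observation is the vector of presence calls over all tracks
(individual x mark); conditional on the hidden state the calls are
independent Bernoullis, so P(o|s) = prod_d e_sd^o_d (1-e_sd)^(1-o_d).
The hidden states are the "global patterns": recurring combinations of
presence across individuals.  Training is Baum-Welch with per-position
scaling; chromosomes are independent sequences sharing parameters.
Decoding assigns each bin the state with maximal posterior probability,
giving one genome annotation universal to all individuals.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    EMISSION_EPS,
    BinaryCallMatrix,
    GenomeAnnotation,
    GlobalPatternModel,
)

__all__ = [
    "fit",
    "log_likelihood",
    "posterior",
    "annotate",
    "subset_decode",
]


def _forward_py(Bs, init, trans):
    T, k = Bs.shape
    alpha = np.empty((T, k))
    c = np.empty(T)
    a = init * Bs[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * Bs[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    return alpha, c


def _backward_py(Bs, trans, c):
    T, k = Bs.shape
    beta = np.empty((T, k))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (Bs[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


_forward, _backward = _forward_py, _backward_py
try:  # numba speeds the O(T k^2) scans up considerably when available
    import numba as _nb

    _forward = _nb.njit(cache=True)(_forward_py)
    _backward = _nb.njit(cache=True)(_backward_py)
except ImportError:  # pragma: no cover - exercised only without numba
    pass


def _obs_logprob(calls: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """T x k log P(o_t | s) under independent Bernoullis."""
    e = np.clip(emission, EMISSION_EPS, 1 - EMISSION_EPS)
    loge = np.log(e)
    log1me = np.log1p(-e)
    calls = calls.astype(float)
    return calls @ loge.T + (1.0 - calls) @ log1me.T


def _scaled_obs(calls: np.ndarray, emission: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    logB = _obs_logprob(calls, emission)
    m = logB.max(axis=1)
    return np.exp(logB - m[:, None]), m


def _sequences(calls: BinaryCallMatrix) -> list[np.ndarray]:
    return [calls.calls[sl] for sl in calls.bin_table.chrom_slices().values()]


def _check_tracks(model: GlobalPatternModel, calls: BinaryCallMatrix) -> None:
    if model.track_ids != calls.track_ids:
        raise ValueError("model tracks do not match call-matrix tracks")


def _forward_backward_seq(seq, model, emission=None):
    e = model.emission if emission is None else emission
    Bs, m = _scaled_obs(seq, e)
    alpha, c = _forward(Bs, model.initial, model.transition)
    beta = _backward(Bs, model.transition, c)
    ll = float(np.log(c).sum() + m.sum())
    return alpha, beta, c, Bs, ll


def log_likelihood(model: GlobalPatternModel, calls: BinaryCallMatrix) -> float:
    """Total log-likelihood of the calls (chromosomes independent)."""
    _check_tracks(model, calls)
    total = 0.0
    for seq in _sequences(calls):
        Bs, m = _scaled_obs(seq, model.emission)
        _, c = _forward(Bs, model.initial, model.transition)
        total += float(np.log(c).sum() + m.sum())
    return total


def posterior(model: GlobalPatternModel, calls: BinaryCallMatrix) -> np.ndarray:
    """bins x k posterior state probabilities (rows sum to 1)."""
    _check_tracks(model, calls)
    out = []
    for seq in _sequences(calls):
        alpha, beta, _, _, _ = _forward_backward_seq(seq, model)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        out.append(gamma)
    return np.concatenate(out, axis=0)


def annotate(model: GlobalPatternModel, calls: BinaryCallMatrix) -> GenomeAnnotation:
    """Assign each bin the most likely state (posterior argmax, ties to
    the smallest state id).  State ids are 1-based."""
    gamma = posterior(model, calls)
    states = gamma.argmax(axis=1) + 1  # argmax takes the first maximum
    return GenomeAnnotation(states, calls.bins.copy())


def _init_params(k: int, n_tracks: int, rng: np.random.Generator):
    emission = rng.uniform(0.2, 0.8, size=(k, n_tracks))
    initial = rng.dirichlet(np.full(k, 50.0))
    transition = rng.dirichlet(np.full(k, 50.0), size=k)
    return initial, transition, emission


def _baum_welch(
    seqs: list[np.ndarray],
    k: int,
    tracks: pd.DataFrame,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[GlobalPatternModel, list[float]]:
    n_tracks = seqs[0].shape[1]
    initial, transition, emission = _init_params(k, n_tracks, rng)
    trace: list[float] = []
    ll_old = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        init_acc = np.zeros(k)
        xi_acc = np.zeros((k, k))
        em_num = np.zeros((k, n_tracks))
        em_den = np.zeros(k)
        model = GlobalPatternModel(initial, transition, emission, tracks)
        for seq in seqs:
            alpha, beta, c, Bs, ll_seq = _forward_backward_seq(seq, model)
            ll += ll_seq
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            init_acc += gamma[0]
            if len(seq) > 1:
                w = Bs[1:] * beta[1:] / c[1:, None]
                xi_acc += transition * (alpha[:-1].T @ w)
            em_num += gamma.T @ seq
            em_den += gamma.sum(axis=0)
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            break
        ll_old = ll
        initial = init_acc / init_acc.sum()
        rows = xi_acc.sum(axis=1, keepdims=True)
        transition = np.where(rows > 0, xi_acc / np.maximum(rows, 1e-300), 1.0 / k)
        emission = np.clip(em_num / np.maximum(em_den[:, None], 1e-300), EMISSION_EPS, 1 - EMISSION_EPS)
    final = GlobalPatternModel(initial, transition, emission, tracks)
    return final, trace


def fit(
    calls: BinaryCallMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    restarts: int = 1,
) -> tuple[GlobalPatternModel, list[float]]:
    """Train a k-state model by Baum-Welch; best of ``restarts`` returned.

    Initialization is seeded: emissions uniform in [0.2, 0.8], initial
    and transition near-uniform with Dirichlet jitter.  Stops when the
    relative log-likelihood change drops below ``tol`` or after
    ``max_iter`` iterations.  Returns the model and the per-iteration
    log-likelihood trace of the winning restart.
    """
    if len(calls.bins) == 0:
        raise ValueError("empty call matrix")
    if k < 1 or k > len(calls.bins):
        raise ValueError("k must satisfy 1 <= k <= number of bins")
    seqs = _sequences(calls)
    if k > 1 and len(np.unique(calls.calls, axis=0)) == 1:
        warnings.warn("all observation rows identical; states will duplicate", stacklevel=2)
    best: Optional[tuple[GlobalPatternModel, list[float]]] = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        model, trace = _baum_welch(seqs, k, calls.tracks.copy(), rng, max_iter, tol)
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
    model, trace = best
    model.meta.update(
        {"k": k, "seed": seed, "iterations": len(trace), "final_ll": trace[-1], "restarts": restarts}
    )
    return model, trace


def subset_decode(
    model: GlobalPatternModel,
    calls: BinaryCallMatrix,
    track_subset: Sequence[str],
) -> tuple[GenomeAnnotation, np.ndarray]:
    """Re-annotate using only a subset of tracks; report recovery.

    The Bernoulli factors of tracks outside the subset are dropped
    (marginalized).  Returns the subset annotation and a k x k confusion
    matrix whose entry (i, j) is the fraction of bins annotated i by the
    full track set that the subset annotates j; rows sum to 1 (rows of
    states with no full-set bins are left at 0).
    """
    _check_tracks(model, calls)
    ids = model.track_ids
    idx = []
    for t in track_subset:
        if t not in ids:
            raise ValueError(f"unknown track {t!r}")
        idx.append(ids.index(t))
    if not idx:
        raise ValueError("track subset must be nonempty")
    idx = sorted(set(idx))

    full = annotate(model, calls)

    sub_emission = model.emission[:, idx]
    sub_tracks = model.tracks.iloc[idx].reset_index(drop=True)
    sub_model = GlobalPatternModel(
        model.initial.copy(), model.transition.copy(), sub_emission, sub_tracks
    )
    sub_calls = BinaryCallMatrix(calls.calls[:, idx], calls.bins.copy(), sub_tracks)
    sub = annotate(sub_model, sub_calls)

    k = model.k
    confusion = np.zeros((k, k))
    np.add.at(confusion, (full.states - 1, sub.states - 1), 1.0)
    rows = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        confusion = np.where(rows > 0, confusion / np.maximum(rows, 1), 0.0)
    return sub, confusion
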