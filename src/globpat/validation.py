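"""Internal-consistency and robustness diagnostics on emission matrices.

Because marks known to co-occur in the genome should produce correlated
per-individual emission vectors in the same state even though training
is agnostic to mark labels, cross-mark correlation is an internal
validity check.  Robustness is checked by fitting models on disjoint
genome subsets and greedily matching states by Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GlobalPatternModel

__all__ = [
    "StateMatching",
    "mark_pair_correlation",
    "greedy_match_states",
    "classify_singletons",
]


@dataclass
class StateMatching:
    """Greedy pairing of states between two models."""

    pairs: list  # (state_a, state_b, rho), 1-based state ids
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)

    @property
    def median_rho(self) -> float:
        return float(np.median([r for _, _, r in self.pairs]))


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties; nan -> 0 for constant input."""
    r = stats.spearmanr(x, y).statistic
    return float(r) if np.isfinite(r) else 0.0


def mark_pair_correlation(model: GlobalPatternModel) -> pd.DataFrame:
    """Median (over states) Spearman correlation across individuals for
    every pair of marks' emission sub-vectors.

    Requires the same individual ordering within each mark block, which
    the track table guarantees by construction.
    """
    marks = model.marks
    if len(marks) < 2:
        raise ValueError("need >= 2 marks")
    blocks = {}
    for mark in marks:
        block, individuals = model.mark_block(mark)
        if len(individuals) < 3:
            raise ValueError(f"mark {mark!r} has fewer than 3 individuals")
        blocks[mark] = (block, individuals)
    rows = []
    for m1, m2 in combinations(marks, 2):
        b1, ind1 = blocks[m1]
        b2, ind2 = blocks[m2]
        if ind1 != ind2:
            raise ValueError("individual ordering differs between mark blocks")
        rhos = [_spearman(b1[s], b2[s]) for s in range(model.k)]
        rows.append((m1, m2, float(np.median(rhos))))
    return pd.DataFrame(rows, columns=["mark_a", "mark_b", "median_rho"])


def greedy_match_states(model_a: GlobalPatternModel, model_b: GlobalPatternModel) -> StateMatching:
    """Iteratively pair the globally most correlated unmatched states.

    Spearman correlation of emission vectors over tracks; deterministic
    tie-break by (state_a id, state_b id).  Leftover states of the
    larger model are reported unmatched.
    """
    if model_a.track_ids != model_b.track_ids:
        raise ValueError("models must share track ordering")
    ka, kb = model_a.k, model_b.k
    corr = np.empty((ka, kb))
    ra = stats.rankdata(model_a.emission, axis=1)
    rb = stats.rankdata(model_b.emission, axis=1)
    ra = (ra - ra.mean(axis=1, keepdims=True)) / np.maximum(ra.std(axis=1, keepdims=True), 1e-300)
    rb = (rb - rb.mean(axis=1, keepdims=True)) / np.maximum(rb.std(axis=1, keepdims=True), 1e-300)
    corr = ra @ rb.T / model_a.n_tracks
    avail_a = set(range(ka))
    avail_b = set(range(kb))
    pairs = []
    while avail_a and avail_b:
        best = None
        for i in sorted(avail_a):
            for j in sorted(avail_b):
                c = corr[i, j]
                if best is None or c > best[0] + 1e-15:
                    best = (c, i, j)
        c, i, j = best
        pairs.append((i + 1, j + 1, float(c)))
        avail_a.discard(i)
        avail_b.discard(j)
    return StateMatching(
        pairs,
        unmatched_a=sorted(s + 1 for s in avail_a),
        unmatched_b=sorted(s + 1 for s in avail_b),
    )


def classify_singletons(
    model: GlobalPatternModel,
    mark: str | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Label each state singleton/nonsingleton.

    A singleton state has exactly one individual with emission strictly
    greater than ``threshold`` (within the given mark block; required
    for multi-mark models).  States where no individual exceeds the
    threshold are nonsingleton.
    """
    if mark is None:
        marks = model.marks
        if len(marks) != 1:
            raise ValueError("specify mark for a multi-mark model")
        mark = marks[0]
    block, _ = model.mark_block(mark)
    n_above = (block > threshold).sum(axis=1)
    label = np.where(n_above == 1, "singleton", "nonsingleton")
    return pd.DataFrame(
        {"state": np.arange(1, model.k + 1), "n_above": n_above, "label": label}
    )
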