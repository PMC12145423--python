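"""Overlap enrichment of the global-pattern annotation with interval sets.

Counting is base-level: a state's fold enrichment for an annotation
label is the fraction of the state's bases overlapping the label,
divided by the label's genome fraction.  Significance is a two-sided
exact binomial test (n = state bases, success probability = label
genome fraction), corrected by Benjamini-Hochberg within each
annotation source.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BIN_SIZE, GenomeAnnotation

__all__ = [
    "merge_intervals",
    "overlap_enrichment",
    "label_states",
    "tss_flank_intervals",
    "fisher_overlap",
]


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome (and label, if
    a label column is present).  Coordinates are 0-based half-open."""
    if (intervals["start"] >= intervals["end"]).any():
        raise ValueError("intervals require start < end")
    keys = ["label", "chrom"] if "label" in intervals.columns else ["chrom"]
    rows = []
    for key, grp in intervals.groupby(keys, sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((*key, cur_s, cur_e) if isinstance(key, tuple) else (key, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((*key, cur_s, cur_e) if isinstance(key, tuple) else (key, cur_s, cur_e))
    cols = keys + ["start", "end"]
    out = pd.DataFrame(rows, columns=cols)
    return out[[c for c in ["chrom", "start", "end", "label"] if c in out.columns]]


def _per_bin_overlap(annotation: GenomeAnnotation, intervals: pd.DataFrame) -> np.ndarray:
    """Bases of each annotation bin overlapped by the (merged) intervals."""
    overlap = np.zeros(len(annotation.bins))
    slices = annotation.bin_table.chrom_slices()
    starts = annotation.bins["start"].to_numpy()
    for chrom, grp in intervals.groupby("chrom"):
        if chrom not in slices:
            continue
        sl = slices[chrom]
        lo = starts[sl.start]
        hi = starts[sl.stop - 1] + BIN_SIZE
        for s, e in zip(grp["start"], grp["end"]):
            s, e = max(s, lo), min(e, hi)
            if s >= e:
                continue
            b0 = (s - lo) // BIN_SIZE
            b1 = (e - 1 - lo) // BIN_SIZE
            if b0 == b1:
                overlap[sl.start + b0] += e - s
            else:
                overlap[sl.start + b0] += lo + (b0 + 1) * BIN_SIZE - s
                overlap[sl.start + b1] += e - (lo + b1 * BIN_SIZE)
                if b1 > b0 + 1:
                    overlap[sl.start + b0 + 1 : sl.start + b1] += BIN_SIZE
    return overlap


def overlap_enrichment(
    annotation: GenomeAnnotation,
    intervals: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per (state, label) fold enrichment with binomial p and BH q.

    ``intervals`` needs columns chrom/start/end and optionally label
    (unlabeled sets are treated as one label "interval").  Labels with
    zero overlap-able bases raise; states with no bins are omitted.
    A pair is significant when fold > 1 and q < ``fdr``.
    """
    intervals = intervals.copy()
    if "label" not in intervals.columns:
        intervals["label"] = "interval"
    intervals = merge_intervals(intervals)
    genome_bases = len(annotation.bins) * BIN_SIZE
    states = annotation.states
    k = annotation.k
    state_bases = np.bincount(states, minlength=k + 1)[1:] * BIN_SIZE

    rows = []
    for label, grp in intervals.groupby("label", sort=True):
        per_bin = _per_bin_overlap(annotation, grp)
        label_bases = per_bin.sum()
        if label_bases == 0:
            raise ValueError(f"label {label!r} covers no bases of the annotated genome")
        frac = label_bases / genome_bases
        ov = np.zeros(k + 1)
        np.add.at(ov, states, per_bin)
        for s in range(1, k + 1):
            nb = state_bases[s - 1]
            if nb == 0:
                continue  # empty state: fold undefined, reported absent
            obs = ov[s]
            fold = (obs / nb) / frac
            p = stats.binomtest(int(round(obs)), int(nb), frac).pvalue
            rows.append((s, label, fold, p, obs, nb, frac))
    out = pd.DataFrame(
        rows, columns=["state", "label", "fold", "p", "overlap_bases", "state_bases", "genome_frac"]
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = (out["fold"] > 1) & (out["q"] < fdr)
    else:
        out["q"] = []
        out["significant"] = []
    return out


def label_states(
    annotation: GenomeAnnotation,
    reference: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Annotate each state with its most enriched significant reference label.

    Among labels with fold > 1 and q < ``fdr`` the maximal-fold label is
    chosen (ties lexicographic); states with no significant label get
    "unlabeled".
    """
    enr = overlap_enrichment(annotation, reference, fdr=fdr)
    sig = enr[enr["significant"]]
    best = {}
    for s, grp in sig.groupby("state"):
        grp = grp.sort_values(["fold", "label"], ascending=[False, True])
        best[s] = grp.iloc[0]["label"]
    rows = [(s, best.get(s, "unlabeled")) for s in range(1, annotation.k + 1)]
    return pd.DataFrame(rows, columns=["state", "label"])


def tss_flank_intervals(
    tss_table: pd.DataFrame,
    chrom_sizes: dict,
    flank: int = 2000,
) -> pd.DataFrame:
    """Promoter-like intervals: +/- ``flank`` bases around each TSS,
    clipped to chromosome bounds, overlapping flanks merged."""
    rows = []
    for _, row in tss_table.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        size = chrom_sizes[chrom]
        if pos > size or pos < 0:
            raise ValueError(f"TSS at {chrom}:{pos} beyond chromosome length {size}")
        rows.append((chrom, max(pos - flank, 0), min(pos + flank, size)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return merge_intervals(out)


def fisher_overlap(set_a, set_b, universe) -> dict:
    """Two-sided Fisher's exact test for overlap of two feature sets.

    fold = observed overlap / expected (|A||B|/|U|).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(universe) - both - only_a - only_b
    odds, p = stats.fisher_exact([[both, only_a], [only_b, neither]], alternative="two-sided")
    expected = len(a) * len(b) / len(universe)
    fold = both / expected if expected > 0 else np.nan
    return {
        "overlap": both,
        "expected": expected,
        "fold": fold,
        "odds_ratio": float(odds),
        "p": float(p),
    }
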