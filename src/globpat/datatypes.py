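"""Core in-memory containers shared across the pipeline.

The pipeline works on a genome partitioned into fixed-width (200 bp)
non-overlapping bins.  Each ChIP-seq data set ("track") is one
(individual, mark) pair; the stacked model treats every track as a
separate observation dimension, so a single hidden-state annotation is
shared by all individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_SIZE = 200

__all__ = [
    "BIN_SIZE",
    "BinTable",
    "BinnedTrackMatrix",
    "BinaryCallMatrix",
    "GlobalPatternModel",
    "GenomeAnnotation",
    "GenotypeMatrix",
    "track_ids",
]


def track_ids(tracks: pd.DataFrame) -> list[str]:
    """Canonical string id for each track: ``"<individual>_<mark>"``."""
    return [f"{i}_{m}" for i, m in zip(tracks["individual"], tracks["mark"])]


def _check_bins(bins: pd.DataFrame) -> pd.DataFrame:
    bins = bins.reset_index(drop=True)
    required = {"chrom", "start"}
    if not required.issubset(bins.columns):
        raise ValueError(f"bin table needs columns {sorted(required)}")
    if "end" not in bins.columns:
        bins = bins.assign(end=bins["start"] + BIN_SIZE)
    if not (bins["end"] - bins["start"] == BIN_SIZE).all():
        raise ValueError(f"all bins must be {BIN_SIZE} bp wide")
    key = bins[["chrom", "start"]]
    if key.duplicated().any():
        raise ValueError("duplicate bins")
    return bins


@dataclass
class BinTable:
    """Ordered genomic bins, sorted by (chrom, start), contiguous per chromosome."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _check_bins(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice for each chromosome, in table order."""
        out: dict[str, slice] = {}
        chrom = self.frame["chrom"].to_numpy()
        boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(chrom)]])
        for s, e in zip(starts, ends):
            c = chrom[s]
            if c in out:
                raise ValueError(f"chromosome {c!r} rows are not contiguous")
            out[c] = slice(int(s), int(e))
        return out


@dataclass
class BinnedTrackMatrix:
    """bins x tracks signal matrix.

    ``bins`` carries (chrom, start, end); ``tracks`` has one row per
    data set with columns (individual, mark).
    """

    values: np.ndarray
    bins: pd.DataFrame
    tracks: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bins = _check_bins(self.bins)
        self.tracks = self.tracks.reset_index(drop=True)
        if self.values.shape != (len(self.bins), len(self.tracks)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.bins)} bins x {len(self.tracks)} tracks"
            )
        if np.any(self.values < 0):
            raise ValueError("signal values must be nonnegative")

    @property
    def track_ids(self) -> list[str]:
        return track_ids(self.tracks)

    @property
    def bin_table(self) -> BinTable:
        return BinTable(self.bins)

    def mark_groups(self) -> dict[str, np.ndarray]:
        """Column indices per mark, preserving track order."""
        out: dict[str, np.ndarray] = {}
        for mark in dict.fromkeys(self.tracks["mark"]):
            out[mark] = np.flatnonzero((self.tracks["mark"] == mark).to_numpy())
        return out


@dataclass
class BinaryCallMatrix:
    """Presence/absence calls per bin per track (same metadata as the source)."""

    calls: np.ndarray
    bins: pd.DataFrame
    tracks: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if not np.isin(self.calls, [0, 1]).all():
            raise ValueError("calls must be 0/1")
        self.calls = self.calls.astype(np.uint8)
        self.bins = _check_bins(self.bins)
        self.tracks = self.tracks.reset_index(drop=True)
        if self.calls.shape != (len(self.bins), len(self.tracks)):
            raise ValueError("calls shape inconsistent with bin/track metadata")

    @property
    def track_ids(self) -> list[str]:
        return track_ids(self.tracks)

    @property
    def bin_table(self) -> BinTable:
        return BinTable(self.bins)


EMISSION_EPS = 1e-6


@dataclass
class GlobalPatternModel:
    """Stacked HMM over binary tracks.

    emission[s, d] is the probability of a presence call for track d
    given hidden state s; these per-track probabilities are the "global
    pattern" parameters used by every downstream association.
    States are numbered 1..k externally; arrays are 0-indexed.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    tracks: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.tracks = self.tracks.reset_index(drop=True)
        k = self.k
        if self.initial.shape != (k,) or self.transition.shape != (k, k):
            raise ValueError("inconsistent parameter shapes")
        if self.emission.shape[1] != len(self.tracks):
            raise ValueError("emission columns != number of tracks")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.max(np.abs(self.transition.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if np.any(self.emission < EMISSION_EPS) or np.any(self.emission > 1 - EMISSION_EPS):
            self.emission = np.clip(self.emission, EMISSION_EPS, 1 - EMISSION_EPS)

    @property
    def k(self) -> int:
        return self.emission.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.emission.shape[1]

    @property
    def marks(self) -> list[str]:
        return list(dict.fromkeys(self.tracks["mark"]))

    @property
    def track_ids(self) -> list[str]:
        return track_ids(self.tracks)

    def mark_block(self, mark: str) -> tuple[np.ndarray, list]:
        """(k x n_individuals emission sub-matrix, individual ids) for one mark."""
        sel = (self.tracks["mark"] == mark).to_numpy()
        if not sel.any():
            raise KeyError(f"unknown mark {mark!r}")
        individuals = list(self.tracks.loc[sel, "individual"])
        return self.emission[:, sel], individuals


@dataclass
class GenomeAnnotation:
    """One hidden-state id (1-based) per 200 bp bin, universal to all individuals."""

    states: np.ndarray
    bins: pd.DataFrame

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.bins = _check_bins(self.bins)
        if self.states.shape != (len(self.bins),):
            raise ValueError("one state per bin required")
        if self.states.min() < 1:
            raise ValueError("state ids are 1-based")

    @property
    def k(self) -> int:
        return int(self.states.max())

    @property
    def bin_table(self) -> BinTable:
        return BinTable(self.bins)

    def to_bed(self) -> pd.DataFrame:
        """BED4 frame with adjacent same-state bins merged (0-based half-open)."""
        rows = []
        chrom = self.bins["chrom"].to_numpy()
        start = self.bins["start"].to_numpy()
        end = self.bins["end"].to_numpy()
        st = self.states
        i = 0
        n = len(st)
        while i < n:
            j = i
            while (
                j + 1 < n
                and chrom[j + 1] == chrom[i]
                and st[j + 1] == st[i]
                and start[j + 1] == end[j]
            ):
                j += 1
            rows.append((chrom[i], int(start[i]), int(end[j]), f"GP{st[i]}"))
            i = j + 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass
class GenotypeMatrix:
    """SNP x individual dosage matrix in {0,1,2} with per-SNP metadata."""

    dosages: np.ndarray
    snps: pd.DataFrame  # columns: chrom, pos, id, ref, alt
    individuals: list

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not np.isin(self.dosages, [0, 1, 2]).all():
            raise ValueError("dosages must be 0/1/2 (no missing values)")
        self.dosages = self.dosages.astype(np.int8)
        self.snps = self.snps.reset_index(drop=True)
        self.individuals = list(self.individuals)
        if self.dosages.shape != (len(self.snps), len(self.individuals)):
            raise ValueError("dosage shape inconsistent with metadata")

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, in [0, 0.5]."""
        af = self.dosages.mean(axis=1) / 2.0
        return np.minimum(af, 1.0 - af)

    def subset_individuals(self, keep: list) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in keep]
        return GenotypeMatrix(self.dosages[:, idx], self.snps.copy(), keep)
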