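"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates multi-individual histone-modification data: a
first-order Markov chain of hidden "global pattern" states along 200 bp
genome bins; per-state, per-track Bernoulli presence probabilities with
a block architecture (each state is active in a subset of individuals,
concordantly across marks); and read counts drawn from a two-rate
Poisson gated by the presence variable, with multiplicative per-track
covariate effects.  Genotypes, expression, protein levels, intervals
and case/control labels are coupled to the emission level so that every
downstream association stage has a planted, recoverable truth.

Default parameters mirror the lymphoblastoid study design this package
targets: 75 individuals, three marks (H3K27ac, H3K4me1, H3K4me3),
200 bp bins, common variants with MAF > 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import BIN_SIZE, BinnedTrackMatrix, GenotypeMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_truth",
    "simulate_counts",
    "simulate_calls",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotype_labels",
    "simulate_intervals",
    "effective_emissions",
    "block_emission_architecture",
]

# substream tags so each simulate_* draws from an independent stream of
# the single global seed
_STREAMS = {
    "truth": 0,
    "counts": 1,
    "genotypes": 2,
    "expression": 3,
    "intervals": 4,
    "covariates": 5,
    "phenotype": 6,
    "arch": 7,
    "calls": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``emission_arch`` may be an explicit (k_true x D) probability matrix
    or None, in which case a block architecture is generated: each state
    is active (presence probability ``p_active``) in a random subset of
    individuals and inactive (``p_inactive``) elsewhere, with the active
    subset shared across marks (mark concordance).
    """

    n_individuals: int = 75
    marks: Sequence[str] = ("H3K27ac", "H3K4me1", "H3K4me3")
    n_bins: int = 20_000
    n_chroms: int = 2
    k_true: int = 8
    self_transition: float = 0.9
    emission_arch: Optional[np.ndarray] = None
    p_active: float = 0.9
    p_inactive: float = 0.02
    active_fraction: float = 0.25
    mark_concordance: bool = True
    # state 1 is a quiescent background pattern (inactive in everyone)
    # occupying most of the genome, as in real chromatin annotations
    background_state: bool = True
    background_weight: float = 0.85
    count_rates: tuple[float, float] = (1.0, 40.0)  # (lambda_low, lambda_high)
    covariates: Sequence[tuple[str, float]] = (("seq_depth", 0.3), ("rsc", -0.2))
    # genotypes
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    gqtl_plan: Sequence[tuple] = ()  # (snp_idx, state_1based, shift[, mark])
    # expression
    n_genes: int = 100
    expr_plan: Sequence[tuple] = ()  # (gene_idx, state_1based, mark, slope, noise_sd)
    expr_noise_sd: float = 1.0
    # phenotype
    pheno_plan: Optional[tuple[Sequence[int], float]] = None  # (states_1based, case_shift)
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.count_rates
        if not (hi > lo > 0):
            raise ValueError("count_rates must satisfy lambda_high > lambda_low > 0")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if not (0.0 <= self.self_transition <= 1.0):
            raise ValueError("self_transition must be a probability")
        for p in (self.p_active, self.p_inactive):
            if not (0.0 <= p <= 1.0):
                raise ValueError("emission probabilities must lie in [0, 1]")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_chroms < 1 or self.n_bins < self.n_chroms:
            raise ValueError("need at least one bin per chromosome")
        if self.emission_arch is not None:
            arch = np.asarray(self.emission_arch, dtype=float)
            if arch.shape != (self.k_true, self.n_tracks):
                raise ValueError(
                    f"emission_arch shape {arch.shape} != (k_true, n_tracks) = "
                    f"({self.k_true}, {self.n_tracks})"
                )
            if arch.min() < 0 or arch.max() > 1:
                raise ValueError("emission_arch entries must be probabilities")
            self.emission_arch = arch

    @property
    def individuals(self) -> list[str]:
        return [f"ind{i:03d}" for i in range(1, self.n_individuals + 1)]

    @property
    def n_tracks(self) -> int:
        return self.n_individuals * len(self.marks)

    @property
    def tracks(self) -> pd.DataFrame:
        """Track table: marks are blocks, individual order identical in each block."""
        rows = [(ind, mark) for mark in self.marks for ind in self.individuals]
        return pd.DataFrame(rows, columns=["individual", "mark"])


@dataclass
class SyntheticTruth:
    """Ground truth realized from a :class:`SyntheticConfig`."""

    state_path: np.ndarray  # per-bin true state, 1-based
    bins: pd.DataFrame
    true_emissions: np.ndarray  # k_true x D presence probabilities
    tracks: pd.DataFrame
    chrom_sizes: dict
    planted_gqtls: list = field(default_factory=list)
    planted_expression_links: list = field(default_factory=list)
    planted_phenotype_states: list = field(default_factory=list)

    def __post_init__(self) -> None:
        k = self.true_emissions.shape[0]
        if self.state_path.min() < 1 or self.state_path.max() > k:
            raise ValueError("state_path values must lie in 1..k_true")
        if self.true_emissions.shape[1] != len(self.tracks):
            raise ValueError("true_emissions columns inconsistent with tracks")


def block_emission_architecture(config: SyntheticConfig) -> np.ndarray:
    """k_true x D presence-probability matrix with a per-state active block.

    Each state draws an active individual subset (>= 1 individual); the
    subset is shared across marks when ``mark_concordance`` is set, and
    drawn independently per mark otherwise.
    """
    rng = _rng(config.seed, "arch")
    n, m = config.n_individuals, len(config.marks)
    arch = np.full((config.k_true, n * m), config.p_inactive, dtype=float)
    first_active = 1 if (config.background_state and config.k_true > 1) else 0
    k_active = config.k_true - first_active
    if k_active == 0:
        return arch
    # every individual is active in exactly the same number of states, so
    # per-track presence rates (hence marginal distributions) agree across
    # individuals -- the assumption quantile normalization relies on
    per_ind = max(1, round(config.active_fraction * k_active))
    per_ind = min(per_ind, k_active)
    total = per_ind * n
    sizes = np.full(k_active, total // k_active)
    sizes[: total % k_active] += 1

    def make_assignment() -> list[np.ndarray]:
        load = np.zeros(n)
        subsets = []
        for size in sizes:
            order = rng.permutation(n)
            chosen = order[np.argsort(load[order], kind="stable")[:size]]
            load[chosen] += 1
            subsets.append(chosen)
        return subsets

    if config.mark_concordance:
        subsets = make_assignment()
        for s, active in zip(range(first_active, config.k_true), subsets):
            for j in range(m):
                arch[s, j * n + active] = config.p_active
    else:
        for j in range(m):
            subsets = make_assignment()
            for s, active in zip(range(first_active, config.k_true), subsets):
                arch[s, j * n + active] = config.p_active
    return arch


def _bin_table(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    per = np.full(config.n_chroms, config.n_bins // config.n_chroms)
    per[: config.n_bins % config.n_chroms] += 1
    chroms, starts = [], []
    sizes = {}
    for c, nb in enumerate(per, start=1):
        name = f"chr{c}"
        chroms.extend([name] * nb)
        starts.extend(range(0, nb * BIN_SIZE, BIN_SIZE))
        sizes[name] = int(nb) * BIN_SIZE
    bins = pd.DataFrame({"chrom": chroms, "start": starts})
    bins["end"] = bins["start"] + BIN_SIZE
    return bins, sizes


def _state_weights(config: SyntheticConfig) -> np.ndarray:
    """Target stationary weights of the state chain (background-heavy by
    default so presence calls stay sparse genome-wide)."""
    k = config.k_true
    if config.background_state and k > 1:
        w = np.full(k, (1.0 - config.background_weight) / (k - 1))
        w[0] = config.background_weight
    else:
        w = np.full(k, 1.0 / k)
    return w


def simulate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Realize the hidden-state path and the true emission matrix.

    Chromosomes are independent chains; the transition matrix keeps
    ``self_transition`` on the diagonal and spreads the remaining mass
    over other states proportional to the target stationary weights, so
    the chain dwells mostly in the quiescent background pattern.
    """
    rng = _rng(config.seed, "truth")
    k = config.k_true
    bins, sizes = _bin_table(config)
    w = _state_weights(config)
    if k == 1:
        path = np.ones(config.n_bins, dtype=np.int64)
    else:
        stay = config.self_transition
        trans = np.empty((k, k))
        for i in range(k):
            off = w.copy()
            off[i] = 0.0
            trans[i] = (1.0 - stay) * off / off.sum()
            trans[i, i] = stay
        cum = trans.cumsum(axis=1)
        path = np.empty(config.n_bins, dtype=np.int64)
        pos = 0
        for chrom, size in sizes.items():
            nb = size // BIN_SIZE
            u = rng.random(nb)
            path[pos] = np.searchsorted(w.cumsum(), rng.random()) + 1
            for t in range(1, nb):
                path[pos + t] = np.searchsorted(cum[path[pos + t - 1] - 1], u[t]) + 1
            pos += nb

    arch = config.emission_arch
    if arch is None:
        arch = block_emission_architecture(config)

    truth = SyntheticTruth(
        state_path=path,
        bins=bins,
        true_emissions=arch,
        tracks=config.tracks,
        chrom_sizes=sizes,
        planted_gqtls=[tuple(g) for g in config.gqtl_plan],
        planted_expression_links=[tuple(e) for e in config.expr_plan],
        planted_phenotype_states=(
            list(config.pheno_plan[0]) if config.pheno_plan is not None else []
        ),
    )
    return truth


def simulate_genotypes(config: SyntheticConfig) -> GenotypeMatrix:
    """Independent biallelic SNPs at Hardy-Weinberg equilibrium.

    Allele frequencies are drawn uniformly from ``maf_range``; dosages
    are Binomial(2, f) per individual.
    """
    rng = _rng(config.seed, "genotypes")
    _, sizes = _bin_table(config)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    dosages = rng.binomial(2, freqs[:, None], size=(config.n_snps, config.n_individuals))
    chrom_names = list(sizes)
    chrom = rng.choice(chrom_names, size=config.n_snps)
    pos = np.array([rng.integers(1, sizes[c]) for c in chrom])
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"snp{i:05d}" for i in range(config.n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(dosages, snps, config.individuals)


def _per_individual_shifts(
    config: SyntheticConfig,
    genotypes: Optional[GenotypeMatrix],
    labels: Optional[pd.Series],
) -> np.ndarray:
    """k_true x D additive shifts of presence probability from planted effects."""
    n, marks = config.n_individuals, list(config.marks)
    shifts = np.zeros((config.k_true, config.n_tracks))
    if config.gqtl_plan:
        if genotypes is None:
            raise ValueError("gqtl_plan requires genotypes")
        for entry in config.gqtl_plan:
            snp, state, shift = entry[0], entry[1], entry[2]
            plan_marks = [entry[3]] if len(entry) > 3 and entry[3] is not None else marks
            dose = genotypes.dosages[snp].astype(float)
            for mk in plan_marks:
                j = marks.index(mk)
                shifts[state - 1, j * n : (j + 1) * n] += dose * shift
    if config.pheno_plan is not None:
        if labels is None:
            raise ValueError("pheno_plan requires case/control labels")
        states, case_shift = config.pheno_plan
        is_case = labels.reindex(config.individuals).to_numpy().astype(float)
        for state in states:
            for j in range(len(marks)):
                shifts[state - 1, j * n : (j + 1) * n] += is_case * case_shift
    return shifts


def effective_emissions(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    genotypes: Optional[GenotypeMatrix] = None,
    labels: Optional[pd.Series] = None,
) -> np.ndarray:
    """True emissions with planted per-individual shifts applied, clamped to [0, 1]."""
    shifts = _per_individual_shifts(config, genotypes, labels)
    return np.clip(truth.true_emissions + shifts, 0.0, 1.0)


def simulate_counts(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    genotypes: Optional[GenotypeMatrix] = None,
    labels: Optional[pd.Series] = None,
) -> tuple[BinnedTrackMatrix, pd.DataFrame]:
    """Draw presence calls and Poisson read counts for every bin x track.

    count ~ Poisson(rate * exp(sum_j beta_j x_dj)) with
    rate = lambda_high when the presence variable fires, lambda_low
    otherwise.  Returns the count matrix and the per-track covariate
    table (standard-normal covariate values, one row per track).
    """
    lam_low, lam_high = config.count_rates
    prob = effective_emissions(truth, config, genotypes, labels)

    cov_rng = _rng(config.seed, "covariates")
    names = [name for name, _ in config.covariates]
    betas = np.array([b for _, b in config.covariates], dtype=float)
    cov_values = cov_rng.standard_normal((config.n_tracks, len(names)))
    cov = pd.DataFrame(cov_values, columns=names)
    cov.insert(0, "track", [f"{i}_{m}" for i, m in zip(truth.tracks["individual"], truth.tracks["mark"])])

    rng = _rng(config.seed, "counts")
    p_bin = prob[truth.state_path - 1, :]  # n_bins x D
    z = rng.random(p_bin.shape) < p_bin
    rate = np.where(z, lam_high, lam_low)
    if len(betas):
        rate = rate * np.exp(cov_values @ betas)[None, :]
    counts = rng.poisson(rate).astype(float)
    mat = BinnedTrackMatrix(counts, truth.bins, truth.tracks)
    return mat, cov


def simulate_calls(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    genotypes: Optional[GenotypeMatrix] = None,
    labels: Optional[pd.Series] = None,
) -> "BinaryCallMatrix":
    """Draw exact Bernoulli presence calls (no count layer).

    Bypasses the Poisson emission and binarization; useful for testing
    the state model in isolation, where the binary calls are its direct
    input.
    """
    from .datatypes import BinaryCallMatrix

    rng = _rng(config.seed, "calls")
    prob = effective_emissions(truth, config, genotypes, labels)
    p_bin = prob[truth.state_path - 1, :]
    z = (rng.random(p_bin.shape) < p_bin).astype(np.uint8)
    return BinaryCallMatrix(z, truth.bins, truth.tracks)


def simulate_phenotype_labels(config: SyntheticConfig) -> pd.Series:
    """Binary case/control labels (1 = case) per individual, seeded."""
    rng = _rng(config.seed, "phenotype")
    n_cases = int(round(config.case_fraction * config.n_individuals))
    idx = rng.permutation(config.n_individuals)[:n_cases]
    labels = np.zeros(config.n_individuals, dtype=int)
    labels[idx] = 1
    return pd.Series(labels, index=config.individuals, name="case")


def simulate_expression(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    emissions: Optional[np.ndarray] = None,
    genotypes: Optional[GenotypeMatrix] = None,
    labels: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x individuals) linearly coupled to emissions.

    Planted genes follow ``expr_plan``: y = slope * e(state, mark) + noise,
    where e(state, mark) is the per-individual emission vector (planted
    gQTL shifts included when genotypes are supplied, so expression is
    genotype-coupled through the epigenome).  Other genes are pure noise.
    Also returns a TSS table (gene, chrom, pos, strand).
    """
    rng = _rng(config.seed, "expression")
    if emissions is None:
        emissions = effective_emissions(truth, config, genotypes, labels)
    n, marks = config.n_individuals, list(config.marks)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    expr = rng.standard_normal((config.n_genes, n)) * config.expr_noise_sd
    for gene_idx, state, mark, slope, noise_sd in config.expr_plan:
        j = marks.index(mark)
        vec = emissions[state - 1, j * n : (j + 1) * n]
        expr[gene_idx] = slope * vec + rng.standard_normal(n) * noise_sd
    chrom_names = list(truth.chrom_sizes)
    chrom = rng.choice(chrom_names, size=config.n_genes)
    pos = np.array([rng.integers(0, truth.chrom_sizes[c]) for c in chrom])
    strand = rng.choice(["+", "-"], size=config.n_genes)
    tss = pd.DataFrame({"gene": genes, "chrom": chrom, "pos": pos, "strand": strand})
    frame = pd.DataFrame(expr, index=genes, columns=config.individuals)
    return frame, tss


def simulate_intervals(
    truth: SyntheticTruth,
    state_ids: Sequence[int],
    coverage_fold: float,
    n_intervals: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """BED intervals overlapping bins of ``state_ids`` at a target fold.

    Each interval covers exactly one 200 bp bin.  Bins in the target
    states receive sampling weight w = F(1-p)/(1-Fp) (others weight 1),
    where p is the genome fraction in the target states, so the expected
    base-level fold enrichment of the interval set equals F.
    """
    in_state = np.isin(truth.state_path, list(state_ids))
    p = in_state.mean()
    if p == 0:
        raise ValueError("target states cover no bins")
    if coverage_fold * p >= 1.0:
        raise ValueError(
            f"fold {coverage_fold} unattainable: target states cover fraction {p:.3f}"
        )
    if coverage_fold < 0:
        raise ValueError("coverage_fold must be nonnegative")
    w = np.ones(len(truth.state_path))
    w[in_state] = coverage_fold * (1.0 - p) / (1.0 - coverage_fold * p)
    w /= w.sum()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["intervals"],)))
    if n_intervals > len(truth.state_path):
        raise ValueError("more intervals requested than bins available")
    try:
        chosen = rng.choice(len(truth.state_path), size=n_intervals, replace=False, p=w)
    except ValueError:
        warnings.warn("sampling intervals with replacement", stacklevel=2)
        chosen = rng.choice(len(truth.state_path), size=n_intervals, replace=True, p=w)
    chosen = np.sort(chosen)
    bed = truth.bins.iloc[chosen][["chrom", "start", "end"]].reset_index(drop=True)
    return bed
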