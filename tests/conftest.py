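import numpy as np
import pandas as pd
import pytest

from globpat.datatypes import BinaryCallMatrix, GlobalPatternModel
from globpat.synthio import SyntheticConfig, simulate_calls, simulate_truth


def make_tracks(n_individuals: int, marks=("H3K27ac",)) -> pd.DataFrame:
    rows = [(f"ind{i:03d}", m) for m in marks for i in range(1, n_individuals + 1)]
    return pd.DataFrame(rows, columns=["individual", "mark"])


def make_bins(n_bins: int, n_chroms: int = 1) -> pd.DataFrame:
    per = [n_bins // n_chroms + (1 if c < n_bins % n_chroms else 0) for c in range(n_chroms)]
    chroms, starts = [], []
    for c, nb in enumerate(per, 1):
        chroms += [f"chr{c}"] * nb
        starts += list(range(0, nb * 200, 200))
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": np.array(starts) + 200})


def make_model(emission, self_transition=0.8, marks=("H3K27ac",)) -> GlobalPatternModel:
    emission = np.asarray(emission, dtype=float)
    k = emission.shape[0]
    n_ind = emission.shape[1] // len(marks)
    trans = np.full((k, k), (1 - self_transition) / max(k - 1, 1))
    np.fill_diagonal(trans, self_transition if k > 1 else 1.0)
    return GlobalPatternModel(
        np.full(k, 1.0 / k), trans, emission, make_tracks(n_ind, marks)
    )


def gqtl_power_config(
    seed: int,
    n_individuals: int = 75,
    n_bins: int = 20_000,
    shift: float = 0.2,
    n_snps: int = 40,
    planted=((0, 5, None),),
) -> SyntheticConfig:
    """Study configuration with detectable planted gQTLs.

    Target states carry a flat base emission (0.1 for every individual),
    so the per-individual emission structure of those states is driven by
    genotype dosage alone; the other states are block-structured.
    """
    rng = np.random.default_rng(seed + 1000)
    k = 5
    arch = np.full((k, n_individuals), 0.02)
    for s in (1, 2):  # block states
        active = rng.choice(n_individuals, n_individuals // 3, replace=False)
        arch[s, active] = 0.9
    arch[3] = 0.1
    arch[4] = 0.1
    plan = [(snp, state, shift) for snp, state, _ in planted]
    return SyntheticConfig(
        n_individuals=n_individuals,
        marks=("H3K27ac",),
        n_bins=n_bins,
        n_chroms=2,
        k_true=k,
        emission_arch=arch,
        background_state=True,
        n_snps=n_snps,
        maf_range=(0.2, 0.5),
        gqtl_plan=plan,
        seed=seed,
    )


def pheno_power_config(
    seed: int,
    n_individuals: int = 40,
    n_bins: int = 20_000,
    shift: float = 0.35,
    states=(3, 4),
) -> SyntheticConfig:
    """Case/control study with a detectable planted case shift.

    The shifted states have a flat base emission so the case/control
    difference is the only cross-individual structure there.
    """
    rng = np.random.default_rng(seed + 2000)
    k = 5
    arch = np.full((k, n_individuals), 0.02)
    active = rng.choice(n_individuals, n_individuals // 3, replace=False)
    arch[1, active] = 0.9
    for s in states:
        arch[s - 1] = 0.1
    return SyntheticConfig(
        n_individuals=n_individuals,
        marks=("H3K27ac",),
        n_bins=n_bins,
        n_chroms=2,
        k_true=k,
        emission_arch=arch,
        pheno_plan=(tuple(states), shift),
        seed=seed,
    )


@pytest.fixture(scope="session")
def separated_truth_and_calls():
    """Well-separated 4-state, 12-track data set used by several HMM tests."""
    rng = np.random.default_rng(42)
    arch = np.where(rng.random((4, 12)) < 0.5, 0.9, 0.05)
    cfg = SyntheticConfig(
        n_individuals=12,
        marks=("H3K27ac",),
        n_bins=20_000,
        n_chroms=2,
        k_true=4,
        emission_arch=arch,
        background_state=False,
        seed=5,
    )
    truth = simulate_truth(cfg)
    calls = simulate_calls(truth, cfg)
    return cfg, truth, calls
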