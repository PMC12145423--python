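"""Genetic association with emission parameters (gQTL analysis).

The emission matrix is split by mark and the per-individual emission
parameters of each (state, mark) are treated as a quantitative
phenotype, regressed on SNP dosage (optionally with genotype principal
components as covariates).  Genome-wide significance uses the Bonferroni
threshold 5e-8 / (m * k) where m is the number of marks and k the
number of global patterns.  The module also selects the model size that
maximizes the gQTL count, scores replication against an independent
model via a Mann-Whitney test against uniformity, and measures
gQTL/eQTL overlap with MAF-matched SNP permutations.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, GlobalPatternModel
from .validation import classify_singletons

__all__ = [
    "linear_association",
    "compute_genotype_pcs",
    "associate_gqtl",
    "select_model",
    "replicate_gqtls",
    "eqtl_overlap_permutation",
    "GWAS_ALPHA",
]

GWAS_ALPHA = 5e-8


def _residualize(M: np.ndarray, C: Optional[np.ndarray]) -> np.ndarray:
    """Remove intercept (and covariate) projections from each row of M."""
    M = M - M.mean(axis=1, keepdims=True)
    if C is not None and C.shape[1]:
        Cc = C - C.mean(axis=0, keepdims=True)
        Q, _ = np.linalg.qr(Cc)
        M = M - (M @ Q) @ Q.T
    return M


def linear_association(
    Y: np.ndarray,
    G: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs OLS slope tests between phenotype rows and predictor rows.

    Y: phenotypes (P x n); G: predictors (S x n); covariates: optional
    n x q matrix.  Both sides are residualized against the intercept and
    covariates (Frisch-Waugh), so the returned beta / t / p match a full
    OLS fit with intercept and covariates.  Returns (beta, t, p), each
    P x S.  Pairs where either side is constant give nan.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = Y.shape[1]
    if G.shape[1] != n:
        raise ValueError("phenotypes and predictors must share individuals")
    q = 0 if covariates is None else covariates.shape[1]
    df = n - 2 - q
    if df < 1:
        raise ValueError(f"not enough individuals (n={n}) for {q} covariates")
    Yr = _residualize(Y, covariates)
    Gr = _residualize(G, covariates)
    sy = np.sqrt((Yr**2).sum(axis=1))
    sg = np.sqrt((Gr**2).sum(axis=1))
    cross = Yr @ Gr.T
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cross / np.outer(sy, sg)
        beta = cross / (sg**2)[None, :]
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = (sy[:, None] == 0) | (sg[None, :] == 0)
    for arr in (beta, t, p):
        arr[bad] = np.nan
    return beta, t, p


def compute_genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int = 20) -> np.ndarray:
    """Top principal-component scores of the standardized dosage matrix,
    one row per individual."""
    X = genotypes.dosages.astype(float)
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    X = X[keep] / sd[keep]
    n_pcs = min(n_pcs, X.shape[1] - 1, X.shape[0])
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    return (Vt[:n_pcs] * s[:n_pcs, None]).T


def _emission_phenotypes(model: GlobalPatternModel) -> tuple[np.ndarray, pd.DataFrame, list]:
    """Stack per-mark emission blocks into a phenotype matrix.

    Returns (P x n matrix, metadata frame with state/mark per row,
    individual ids).  Requires identical individual ordering per mark.
    """
    blocks, meta = [], []
    individuals = None
    for mark in model.marks:
        block, inds = model.mark_block(mark)
        if individuals is None:
            individuals = inds
        elif inds != individuals:
            raise ValueError("individual ordering differs between mark blocks")
        blocks.append(block)
        meta.extend((s + 1, mark) for s in range(model.k))
    Y = np.vstack(blocks)
    meta = pd.DataFrame(meta, columns=["state", "mark"])
    return Y, meta, individuals


def associate_gqtl(
    model: GlobalPatternModel,
    genotypes: GenotypeMatrix,
    covariate_pcs: Optional[np.ndarray] = None,
    maf_min: float = 0.05,
    alpha: float = GWAS_ALPHA,
) -> pd.DataFrame:
    """Test every (SNP, state, mark) triple for dosage association.

    Significance at the Bonferroni threshold ``alpha / (m * k)``;
    ``p_adj`` is the Bonferroni-scaled p (family size m * k, recorded in
    the ``family`` column).  SNPs with MAF below ``maf_min`` or constant
    dosage are excluded.
    """
    Y, meta, individuals = _emission_phenotypes(model)
    geno = genotypes.subset_individuals(individuals)
    keep = geno.maf >= maf_min
    const = geno.dosages.std(axis=1) == 0
    if (keep & const).any():
        warnings.warn("constant-dosage SNP(s) skipped", stacklevel=2)
    keep &= ~const
    G = geno.dosages[keep].astype(float)
    snps = geno.snps.loc[keep].reset_index(drop=True)
    m = len(model.marks)
    family = m * model.k
    threshold = alpha / family
    if G.shape[0] == 0:
        return pd.DataFrame(
            columns=["snp", "chrom", "pos", "state", "mark", "beta", "t", "p", "p_adj", "family", "significant"]
        )
    beta, t, p = linear_association(Y, G, covariate_pcs)
    P_rows, S = beta.shape
    out = pd.DataFrame(
        {
            "snp": np.tile(snps["id"].to_numpy(), P_rows),
            "chrom": np.tile(snps["chrom"].to_numpy(), P_rows),
            "pos": np.tile(snps["pos"].to_numpy(), P_rows),
            "state": np.repeat(meta["state"].to_numpy(), S),
            "mark": np.repeat(meta["mark"].to_numpy(), S),
            "beta": beta.ravel(),
            "t": t.ravel(),
            "p": p.ravel(),
        }
    )
    out["p_adj"] = np.minimum(out["p"] * family, 1.0)
    out["family"] = family
    out["significant"] = out["p"] < threshold
    return out


def select_model(
    models: Sequence[GlobalPatternModel],
    genotypes: GenotypeMatrix,
    covariate_pcs: Optional[np.ndarray] = None,
    maf_min: float = 0.05,
    alpha: float = GWAS_ALPHA,
) -> tuple[GlobalPatternModel, pd.DataFrame]:
    """Choose the model size maximizing the number of significant gQTLs.

    Counts unique (SNP, state, mark) triples; unique SNP counts are also
    reported.  Ties break toward the smaller k.
    """
    if not models:
        raise ValueError("no candidate models")
    rows = []
    for model in models:
        res = associate_gqtl(model, genotypes, covariate_pcs, maf_min, alpha)
        sig = res[res["significant"]]
        rows.append((model.k, len(sig), sig["snp"].nunique()))
    counts = pd.DataFrame(rows, columns=["k", "n_gqtl", "n_unique_snps"])
    best_idx = counts.sort_values(["n_gqtl", "k"], ascending=[False, True]).index[0]
    return models[best_idx], counts


def replicate_gqtls(
    discovery_snps: Sequence[str],
    replication_model: GlobalPatternModel,
    replication_genotypes: GenotypeMatrix,
    mark: Optional[str] = None,
    nonsingleton_only: bool = True,
    covariate_pcs: Optional[np.ndarray] = None,
    maf_min: float = 0.0,
    uniform_size: int = 100_000,
    seed: int = 0,
) -> dict:
    """Score discovery gQTLs in an independent data set.

    Each shared SNP is associated with the replication model's
    nonsingleton states (singletons excluded to boost power, analogous
    to dropping low-MAF SNPs); the per-SNP minimum p is kept and the
    collection is compared with Uniform(0, 1) by a two-sided
    Mann-Whitney U test against a large seeded uniform sample.
    """
    shared = [s for s in discovery_snps if s in set(replication_genotypes.snps["id"])]
    if not shared:
        raise ValueError("no discovery SNPs present in the replication genotypes")
    res = associate_gqtl(replication_model, replication_genotypes, covariate_pcs, maf_min)
    res = res[res["snp"].isin(shared)]
    if nonsingleton_only:
        keep_states = set()
        for mk in replication_model.marks if mark is None else [mark]:
            cls = classify_singletons(replication_model, mark=mk)
            keep_states |= set(cls.loc[cls["label"] == "nonsingleton", "state"])
        res = res[res["state"].isin(keep_states)]
        if res.empty:
            raise ValueError("no nonsingleton states to replicate against")
    per_snp = res.groupby("snp")["p"].min()
    rng = np.random.default_rng(seed)
    uniform = rng.random(uniform_size)
    test = stats.mannwhitneyu(per_snp.to_numpy(), uniform, alternative="two-sided")
    return {
        "per_snp_p": per_snp,
        "mwu_statistic": float(test.statistic),
        "uniformity_p": float(test.pvalue),
        "n_shared": len(per_snp),
    }


def _count_significant_eqtls(P: np.ndarray, cols: np.ndarray, threshold: float) -> int:
    """Genes whose top (minimum-p) SNP within the column set passes the
    Bonferroni threshold."""
    sub = P[:, cols]
    top = np.nanmin(sub, axis=1)
    return int(np.sum(top < threshold))


def eqtl_overlap_permutation(
    gqtl_snps: Sequence[str],
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    maf_bin_width: float = 0.05,
) -> dict:
    """Compare eQTL yield of the gQTL SNP set to MAF-matched random sets.

    The gQTL set is associated with all genes; per gene only the
    top-most significant SNP counts, at Bonferroni ``alpha / n_tests``
    (n_tests = set size x number of genes).  ``n_perm`` random SNP sets
    of the same size and MAF-bin distribution are scored identically;
    the reported percentile is the fraction of permutations yielding
    strictly fewer significant eQTLs than observed.
    """
    shared = [i for i in expression.columns if i in genotypes.individuals]
    if not shared:
        raise ValueError("expression individuals must be a subset of genotype individuals")
    geno = genotypes.subset_individuals(shared)
    expr = expression[shared].to_numpy(dtype=float)
    ids = list(geno.snps["id"])
    id_to_idx = {s: i for i, s in enumerate(ids)}
    set_idx = np.array([id_to_idx[s] for s in gqtl_snps if s in id_to_idx])
    if len(set_idx) == 0:
        raise ValueError("no gQTL SNPs found in the genotype matrix")
    _, _, P = linear_association(expr, geno.dosages.astype(float))
    n_tests = len(set_idx) * expr.shape[0]
    threshold = alpha / n_tests
    observed = _count_significant_eqtls(P, set_idx, threshold)
    result = {"observed": observed, "n_tests": n_tests, "threshold": threshold}
    if n_perm <= 0:
        result.update({"perm_counts": [], "percentile": None})
        return result
    maf = geno.maf
    bins = np.floor(maf / maf_bin_width).astype(int)
    set_bins, set_counts = np.unique(bins[set_idx], return_counts=True)
    rng = np.random.default_rng(seed)
    perm_counts = []
    pool_by_bin = {b: np.flatnonzero(bins == b) for b in set_bins}
    for _ in range(n_perm):
        chosen = []
        for b, cnt in zip(set_bins, set_counts):
            pool = pool_by_bin[b]
            if len(pool) >= cnt:
                chosen.append(rng.choice(pool, size=cnt, replace=False))
            else:
                warnings.warn(
                    f"MAF bin {b} has {len(pool)} SNPs < {cnt}; sampling with replacement",
                    stacklevel=2,
                )
                chosen.append(rng.choice(pool, size=cnt, replace=True))
        perm_counts.append(
            _count_significant_eqtls(P, np.concatenate(chosen), threshold)
        )
    perm_counts = np.array(perm_counts)
    result["perm_counts"] = perm_counts
    result["percentile"] = float(np.mean(perm_counts < observed))
    return result
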