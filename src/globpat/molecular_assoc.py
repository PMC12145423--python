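"""Association of emission parameters with expression, modules, proteins.

Emission parameters of each (state, mark) act as per-individual
quantitative variables; features (genes, module eigengenes, proteins)
measured on an overlapping set of individuals are regressed on them.
The emissions come from the fitted model and are never re-estimated for
the shared-individual subset.  A distance-resolved profile correlates a
gene's expression with the emissions of the pattern annotated at each
100 bp window within +/- 500 kb of the TSS.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BIN_SIZE, GenomeAnnotation, GlobalPatternModel
from .gqtl import linear_association

__all__ = [
    "associate_emissions",
    "distance_profile",
    "module_eigengenes",
    "gene_protein_overlap",
]


def _shared_block(model: GlobalPatternModel, mark: str, measurements: pd.DataFrame):
    block, individuals = model.mark_block(mark)
    shared = [i for i in individuals if i in measurements.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared individuals")
    cols = [individuals.index(i) for i in shared]
    return block[:, cols], shared


def associate_emissions(
    model: GlobalPatternModel,
    mark: str,
    measurements: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per (state, feature) OLS of feature values on emission parameters.

    ``measurements`` is features x individuals.  Two-sided t-test on the
    slope; BH correction within the mark.  States with constant
    emissions over the shared individuals are skipped with a warning.
    """
    block, shared = _shared_block(model, mark, measurements)
    Y = measurements[shared].to_numpy(dtype=float)
    const = block.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} state(s) with constant emissions skipped", stacklevel=2
        )
    states = np.flatnonzero(~const)
    beta, t, p = linear_association(Y, block[states])
    n_feat = Y.shape[0]
    out = pd.DataFrame(
        {
            "feature": np.repeat(measurements.index.to_numpy(), len(states)),
            "state": np.tile(states + 1, n_feat),
            "mark": mark,
            "beta": beta.ravel(),
            "t": t.ravel(),
            "p": p.ravel(),
        }
    )
    ok = out["p"].notna()
    out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < fdr
    return out


def distance_profile(
    annotation: GenomeAnnotation,
    model: GlobalPatternModel,
    mark: str,
    expression: pd.DataFrame,
    tss_table: pd.DataFrame,
    window: int = 100,
    span: int = 500_000,
    by_state: bool = False,
) -> pd.DataFrame:
    """Mean expression-emission Pearson r per signed TSS distance.

    The +/- ``span`` region around each gene's TSS is divided into
    2*span/window equidistant windows (10,000 at the defaults).  Each
    window takes the global pattern of the 200 bp annotation bin
    containing its midpoint, and contributes the Pearson correlation
    between the gene's expression and that pattern's per-individual
    emissions for ``mark``.  Distances are signed relative to strand
    (upstream negative).  Windows beyond chromosome ends are skipped and
    denominators adjusted.  Returns a frame (distance, mean_r, n_genes),
    plus a state column when ``by_state`` is set.
    """
    block, shared = _shared_block(model, mark, expression)
    genes = [g for g in tss_table["gene"] if g in expression.index]
    if not genes:
        raise ValueError("no usable genes with TSS and expression")
    expr = expression.loc[genes, shared].to_numpy(dtype=float)

    # gene x state correlation table, computed once
    E = block - block.mean(axis=1, keepdims=True)
    X = expr - expr.mean(axis=1, keepdims=True)
    se = np.sqrt((E**2).sum(axis=1))
    sx = np.sqrt((X**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (X @ E.T) / np.outer(sx, se)  # genes x k

    n_windows = 2 * span // window
    offsets = -span + window * np.arange(n_windows) + window // 2  # midpoints, genomic
    slices = annotation.bin_table.chrom_slices()
    bin_starts = annotation.bins["start"].to_numpy()

    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows)
    if by_state:
        k = model.k
        sums_s = np.zeros((n_windows, k))
        counts_s = np.zeros((n_windows, k))
    tss = tss_table.set_index("gene")
    for gi, gene in enumerate(genes):
        row = tss.loc[gene]
        chrom = row["chrom"]
        if chrom not in slices:
            continue
        sl = slices[chrom]
        lo = bin_starts[sl.start]
        hi = bin_starts[sl.stop - 1] + BIN_SIZE
        mid = int(row["pos"]) + offsets
        valid = (mid >= lo) & (mid < hi)
        if not valid.any():
            continue
        bidx = sl.start + (mid[valid] - lo) // BIN_SIZE
        st = annotation.states[bidx] - 1
        r = corr[gi, st]
        didx = np.flatnonzero(valid)
        if row.get("strand", "+") == "-":
            didx = n_windows - 1 - didx  # flip so upstream stays negative
        ok = np.isfinite(r)
        np.add.at(sums, didx[ok], r[ok])
        np.add.at(counts, didx[ok], 1)
        if by_state:
            np.add.at(sums_s, (didx[ok], st[ok]), r[ok])
            np.add.at(counts_s, (didx[ok], st[ok]), 1)

    distance = -span + window * np.arange(n_windows) + window // 2
    with np.errstate(invalid="ignore"):
        mean_r = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({"distance": distance, "mean_r": mean_r, "n_genes": counts.astype(int)})
    if by_state:
        with np.errstate(invalid="ignore"):
            ms = np.where(counts_s > 0, sums_s / np.maximum(counts_s, 1), np.nan)
        long = pd.DataFrame(
            {
                "distance": np.repeat(distance, model.k),
                "state": np.tile(np.arange(1, model.k + 1), n_windows),
                "mean_r": ms.ravel(),
                "n_genes": counts_s.ravel().astype(int),
            }
        )
        return out, long
    return out


def module_eigengenes(
    expression: pd.DataFrame,
    module_assignments: pd.Series,
) -> pd.DataFrame:
    """First principal-component summary of each co-expression module.

    ``module_assignments`` maps gene -> module id.  Genes are
    standardized across individuals; the eigengene is the first PC score
    per individual (standardized to mean 0, sd 1), sign-fixed to
    correlate positively with the module's mean expression.  Returns
    modules x individuals; the fraction of module variance explained by
    the first component is exposed in ``.attrs["variance_explained"]``.
    """
    rows = {}
    var_explained = {}
    for module, genes in module_assignments.groupby(module_assignments):
        present = [g for g in genes.index if g in expression.index]
        if len(present) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 genes in the matrix")
        X = expression.loc[present].to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"module {module!r} contains constant gene(s)")
        Z = (X - mu) / sd
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        eig = Vt[0]
        mean_expr = Z.mean(axis=0)
        if np.dot(eig, mean_expr) < 0:
            eig = -eig
        eig = (eig - eig.mean()) / eig.std()
        rows[module] = eig
        var_explained[module] = float(s[0] ** 2 / (s**2).sum())
    out = pd.DataFrame(rows, index=expression.columns).T
    out.attrs["variance_explained"] = var_explained
    return out


def gene_protein_overlap(
    sig_genes,
    sig_proteins,
    universe,
    gene_states: Optional[dict] = None,
    protein_states: Optional[dict] = None,
) -> dict:
    """Fisher overlap of expression- and protein-associated feature sets,
    plus the count sharing at least one common associated state."""
    from .enrichment import fisher_overlap

    result = fisher_overlap(sig_genes, sig_proteins, universe)
    shared_state = 0
    if gene_states is not None and protein_states is not None:
        for f in set(sig_genes) & set(sig_proteins):
            if set(gene_states.get(f, ())) & set(protein_states.get(f, ())):
                shared_state += 1
        result["n_shared_state"] = shared_state
    return result
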