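# globpat

**Global patterns of epigenetic variation across individuals.**

Epigenetic mapping studies profile histone modifications (H3K27ac,
H3K4me1, H3K4me3, ...) across dozens of individuals and find thousands
of positions where chromatin differs between people. Most analyses
treat each position marginally. `globpat` instead asks which
*combinations* of individuals gain or lose a mark together, again and
again, across the genome — recurring **global patterns** that can point
to trans-acting regulators, genetic drivers, and disease-associated
chromatin differences.

The package is aimed at computational biologists working with
multi-individual ChIP-seq cohorts (e.g. lymphoblastoid cell lines, or
case/control brain tissue), and at anyone who wants a fully synthetic,
self-contained testbed for this class of model.

## The model

Histone signal is quantified in 200 bp non-overlapping bins and
binarized into presence calls with a Poisson background model. Every
ChIP-seq data set — one (individual, mark) pair — becomes a separate
binary observation *track*, and all D tracks are **stacked** into one
multivariate hidden Markov model with k states:

- observation model: conditional on hidden state *s*, track calls are
  independent Bernoullis, `P(o | s) = ∏_d e_sd^{o_d} (1 − e_sd)^{1−o_d}`;
- the emission matrix `e ∈ [0,1]^{k×D}` *is* the set of global
  patterns: `e_sd` is the probability of seeing the mark in data set
  *d* given pattern *s*;
- a single genome annotation (argmax posterior state per bin) is shared
  by all individuals.

Training is Baum–Welch with per-position scaling; chromosomes are
independent sequences sharing parameters. Downstream, the
per-individual emission parameters of each (state, mark) are treated as
a quantitative phenotype and associated with:

- **genotypes** (gQTLs): OLS of emissions on SNP dosage, Bonferroni
  threshold `5·10⁻⁸ / (m·k)` for m marks and k states; the model size
  is chosen to maximize the gQTL count;
- **gene expression, co-expression module eigengenes, protein levels**:
  per-mark linear associations at FDR 5%, plus a distance-resolved
  expression–emission correlation profile (10,000 windows of 100 bp
  within ±500 kb of each TSS);
- **case/control status**: two-sided Mann–Whitney U per state with
  min-p permutation family-wise correction, confirmed by covariate-
  adjusted logistic regression;
- **external interval annotations**: base-level fold enrichment with a
  two-sided binomial test and Benjamini–Hochberg FDR.

A first-class synthetic-data module (`globpat.synthio`) generates
cohorts with this exact statistical structure — Markov state paths,
block emission architectures, two-rate Poisson counts with covariate
effects, and planted gQTL / expression / phenotype couplings — so every
stage of the pipeline is verifiable against ground truth.

## Worked example

Run the bundled demo pipeline (simulate → preprocess → fit → select →
validate → gQTL → enrich → associate → phenotype) from a YAML config:

```python
from globpat import pipeline

config = {
    "seed": 7,
    "simulate": {
        "n_individuals": 15, "marks": ["H3K27ac"], "n_bins": 4000,
        "n_chroms": 2, "k_true": 4, "n_snps": 50, "n_genes": 30,
        "pheno_plan": [[3], 0.35],
    },
    "fit": {"k_grid": [4], "restarts": 2},
    "gqtl": {"maf_min": 0.05},
    "enrich": {"target_states": [2], "coverage_fold": 4.0, "n_intervals": 150},
    "pheno": {"n_perm": 150},
}
outdir = pipeline.run(config, "demo_out")
```

The manifest written to `demo_out/manifest.json` records, per stage,
what was computed (this run takes a few seconds):

```
simulate    {'wall_s': 0.06, 'n_bins': 4000, 'n_tracks': 15}
preprocess  {'wall_s': 0.05, 'call_rate': 0.163}
fit         {'wall_s': 0.33, 'k_grid': [4]}
select      {'wall_s': 0.01, 'chosen_k': 4}
pheno       {'wall_s': 0.01, 'n_significant': 1}
```

`call_rate` is the genome-wide fraction of (bin, track) presence calls
after binarization (~16% — signal is sparse, as in real chromatin);
`chosen_k` is the model size maximizing the significant gQTL count;
`n_significant` in the `pheno` stage is the number of states associated
with case/control status after min-p permutation correction — here the
one state carrying the planted case shift.
Artifacts are plain text: `calls.tsv` (binary calls),
`model_k4_emissions.tsv` (the global patterns), `annotation_k4.bed`
(the universal segmentation, `GP<id>` labels), `gqtl_results.tsv`,
`phenotype_assoc.tsv`.

The same stages are available on the command line:

```bash
globpat run --config demo.yaml --outdir demo_out
globpat fit --calls demo_out/calls.tsv --states 4 --seed 7 --out-prefix model
globpat validate singletons --model demo_out/model_k4
```

## Layout

| module | role |
| --- | --- |
| `globpat.synthio` | synthetic cohorts with planted, recoverable truth |
| `globpat.preprocess` | quantile normalization, per-bin quasi-Poisson covariate correction, Poisson-threshold binarization |
| `globpat.hmm_core` | stacked Bernoulli HMM: fit / posterior / annotate / subset decoding |
| `globpat.validation` | mark-pair emission correlation, greedy state matching, singleton states |
| `globpat.gqtl` | gQTL discovery, model-size selection, replication, eQTL overlap permutations |
| `globpat.enrichment` | interval fold enrichment, TSS flanks, Fisher overlap |
| `globpat.molecular_assoc` | expression / module eigengene / protein association, distance profile |
| `globpat.phenotype_assoc` | Mann–Whitney + min-p permutation FWER, logistic check |
| `globpat.pipeline`, `globpat.cli` | YAML-driven orchestration and the `globpat` command |

See `docs/methods.md` for the statistical details, parameter defaults,
and known limitations.
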