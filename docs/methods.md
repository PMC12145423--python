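# Methods

This note documents the statistical model, the procedures each module
implements, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Signal preprocessing

**Binning.** Histone-modification signal is summarized as read counts
in 200 bp non-overlapping bins — roughly one nucleosome plus linker,
the standard resolution for chromatin segmentation.

**Quantile normalization** makes each track's distribution across bins
equal to the mean value of the quantile within its group. Grouping is
per mark (marks differ in genome-wide prevalence; individuals within a
mark are assumed comparable). Tied values receive the mean of their
tied quantile targets — deterministic, but it means exact idempotence
holds only for tie-free (continuous) signal; with heavy ties the second
application perturbs values slightly.

**Covariate correction.** For every bin, a log-link Poisson mean model
`μ_d = exp(β₀ + Σ_j β_j x_dj)` is fit across the tracks of each mark by
IRLS (Newton steps on the Poisson score; at most 50 iterations,
relative deviance tolerance 1e-8 — per-bin fits are tiny so a strict
tolerance is cheap). Quasi-Poisson point estimates coincide with these
estimating equations, so over/under-dispersion affects only standard
errors, which are not used. The corrected value is
`observed · exp(β₀)/μ_d`: the covariate multiplicative term is divided
out and the intercept scale retained, keeping the count scale for the
binarizer. Bins that fail to converge pass through unchanged with a
warning; all-zero bins stay zero. Point estimates are verified exactly
against `statsmodels` GLM Poisson in the test suite.

**Binarization.** Per track, λ is the mean corrected signal over all
bins (genome-wide, not per chromosome) and the call threshold is the
smallest integer c ≥ 1 with `P(X ≥ c) ≤ p` for `X ~ Poisson(λ)`, at
`p = 1e-4` by default. Calls compare continuous corrected values
against the integer threshold with `≥`, mirroring count-threshold
semantics.

**A documented limitation.** The per-bin covariate model cannot see the
hidden presence/absence structure, so when a state's active-individual
subset happens to correlate with a covariate in-sample (unavoidable at
n ≈ 75), the fitted slope absorbs part of that biological structure and
the correction rescales whole (state, track) cells — occasionally
across the hard call threshold. End-to-end, presence frequencies per
(state, track) recover the generating emission probabilities tightly in
aggregate (median error ~0.003; ≥95% of cells within 0.05 at 75
individuals and 5·10⁴ bins) but a handful of cells with extreme
covariate values can deviate grossly. This is a property of per-bin
covariate correction combined with threshold binarization, not of the
implementation; it is the same tension between confounder removal and
biological signal that motivates restricting correction to *known*
covariates rather than unsupervised factors.

## The stacked model

The hidden Markov model treats every (individual, mark) data set as a
separate binary observation dimension. Emissions are independent
Bernoullis given the state; the emission matrix rows are the global
patterns. Fitting is Baum–Welch with per-position scaling (the scaling
constants yield the log-likelihood; log-space is not needed and the
scaled recursions are faster — they are additionally JIT-compiled when
numba is available, with an identical pure-numpy fallback).
Chromosomes are independent sequences sharing parameters; the initial
distribution is shared.

Initialization is seeded random: emissions uniform in [0.2, 0.8],
initial/transition near-uniform with Dirichlet jitter. A
reference-style information-based initialization is deliberately not
reproduced; random restarts (best final log-likelihood wins) mitigate
local optima, and two restarts suffice for the well-separated
architectures used in the recovery experiments. Convergence: 200
iterations maximum or relative log-likelihood change below 1e-4.
Emissions are clamped to [1e-6, 1 − 1e-6].

Decoding is per-bin posterior argmax ("most likely hidden state"),
ties broken toward the smaller state id. Subset decoding drops the
Bernoulli factors of excluded tracks (marginalization) and reports a
row-normalized k × k confusion matrix against the full-track
annotation. Note the tie-break makes truly indistinguishable states
collapse onto the smaller id rather than splitting evenly.

Correctness anchors: posteriors and likelihoods match exhaustive
enumeration over all k^T paths on small instances to 1e-10; the
log-likelihood trace is non-decreasing to 1e-8 relative per step at
5·10⁴ bins × 20 tracks; on well-separated truth (emissions in
{0.05, 0.9}, k=8, D=20, 10⁵ bins) greedy-matched emission error is
≤ 0.05 (measured ~0.007) and annotation accuracy ≥ 90% (measured
~99.9%).

## Validation diagnostics

*Mark-pair correlation*: per state, Spearman correlation (average
ranks for ties) across individuals between two marks' emission
sub-vectors; summarized as the median over all states (no filtering to
high-signal states). *Robustness*: two models fit on disjoint genome
halves are matched greedily — repeatedly pair the globally most
correlated unmatched states (ties by smallest ids); greedy rather than
optimal assignment is intentional. *Singleton states* have exactly one
individual with emission strictly greater than 0.5 (states where no
individual exceeds 0.5 are nonsingleton); singletons are excluded from
replication to boost power, analogous to dropping low-MAF variants.

## Genetic association (gQTLs)

The emission matrix is split by mark; each (state, mark) row is a
quantitative phenotype over individuals. Associations are computed by
residualizing phenotype and dosage against the intercept (and optional
genotype principal components, top 20 from the SVD of the standardized
dosage matrix) and converting correlations to t statistics — exactly
equivalent to full OLS with covariates (Frisch–Waugh), verified against
`statsmodels` OLS. Genome-wide significance uses the Bonferroni
threshold `5·10⁻⁸/(m·k)`. SNPs below the MAF floor (default 5%) or
with constant dosage are excluded.

Model-size selection fits a grid of k values and keeps the model with
the most significant (SNP, state, mark) triples (unique SNP counts are
reported alongside; ties break to smaller k). Replication associates
shared SNPs against the replication model's nonsingleton states, keeps
the per-SNP minimum p, and compares the collection with Uniform(0,1) by
a two-sided Mann–Whitney U test against a seeded uniform reference
sample of 10⁵ draws. eQTL overlap associates the gQTL SNP set with all
genes, keeps the top SNP per gene at Bonferroni 0.05 over the tests
performed, and compares the significant-eQTL count against 100 random
SNP sets matched to the gQTL set's size and MAF distribution in
5-percentage-point bins (sampling without replacement; with replacement
and a warning when a bin is too shallow). The reported percentile is
the fraction of permutations with strictly fewer significant eQTLs.

## Overlap enrichment

Counting is base-level: fold = (bases of state overlapping the label /
bases of state) ÷ (bases of label / genome bases); bins partially
covered contribute their overlapping bases. Significance is the exact
two-sided binomial test (sum of outcome probabilities ≤ the observed
outcome's), n = state bases, success probability = the label's genome
fraction, BH-corrected within each annotation source; a pair is called
at fold > 1 and q < 0.05. States are labeled by their most enriched
significant reference label (ties lexicographic; "unlabeled" if none).
Promoter intervals are TSS ± 2 kb, clipped to chromosome bounds and
merged. Set overlap (e.g. expression- vs protein-associated genes) uses
the two-sided Fisher exact test with fold = observed/expected overlap.

## Molecular association

Expression, module eigengenes, and protein levels are regressed on the
per-individual emissions of each state (restricted to shared
individuals; the emissions are model parameters and are never re-fit
for a subset), with BH FDR 5% within each mark. The distance profile
divides ±500 kb around each TSS into 10,000 windows of 100 bp, assigns
each window the global pattern of the 200 bp bin containing its
midpoint (midpoint assignment is unambiguous for 100 bp windows inside
200 bp bins), computes the Pearson correlation between the gene's
expression and that pattern's emissions, and averages per signed
distance (upstream negative, strand-aware; windows beyond chromosome
ends are dropped with denominators adjusted; a per-(distance, state)
breakdown is available via `by_state=True`). Module eigengenes are the
first principal-component scores of the standardized module submatrix,
standardized and sign-anchored to correlate positively with the
module's mean expression; module *construction* is an input, not
implemented here.

## Phenotype association

Each state's emissions are compared between cases and controls with a
two-sided Mann–Whitney U test — exact enumeration when a group has
fewer than 8 individuals and the total sample is small enough to
enumerate (≤ 14; the exact path handles ties by enumerating rank-sum
assignments), otherwise the normal approximation with tie correction.
Family-wise error over states is controlled by label-shuffling min-p
permutation: each permutation re-scores all states and retains the
minimum p; adjusted p = fraction of null minima strictly below the
observed p ("more significant than" read as strict), with a
(1+count)/(1+n_perm) smoothed variant reported so a true floor is not
mistaken for exactly zero. The default 1000 permutations balances
resolution (minimum nonzero adjusted p of 0.001) against cost; ranks
are precomputed once per state, so permutations are matrix products.
A logistic regression of status on the state's emissions plus
covariates (Wald z-test on the emission coefficient, `statsmodels`
Logit) confirms rank-test hits while adjusting directly for
confounders; perfect separation is reported as non-convergence with no
p-value.

## The synthetic generator

`synthio` emulates: a first-order Markov state path over 200 bp bins
(chromosomes independent, constant self-transition probability 0.9 by
default → mean segment ~2 kb); per-state per-track Bernoulli presence
probabilities with a block architecture; Poisson counts gated by
presence (rate λ_low = 1 absent, λ_high = 40 present — a strong,
well-enriched library) with multiplicative per-track covariate effects
(defaults: sequencing-depth-like +0.3 and RSC-like −0.2 on standard
normal covariate values); Hardy–Weinberg biallelic genotypes; and
planted couplings — gQTLs shift a state's per-individual presence
probability by dosage × shift (clamped to [0,1]; truth lives at the
emission level, so count data inherit it), expression follows
`slope · e(state, mark) + noise`, case status shifts chosen states'
presence for cases. Defaults mirror the motivating study design: 75
individuals, marks (H3K27ac, H3K4me1, H3K4me3), mark-concordant
architectures, common variants with MAF in [0.05, 0.5]. A single seed
feeds independent per-operation substreams, so each `simulate_*` call
is reproducible on its own.

Architecture defaults and their rationale:

- **state 1 is a quiescent background pattern** (presence 0.02 in
  everyone). With a constant self-transition the chain's stationary
  distribution is proportional to `w(1−w)` in the off-diagonal jump
  weights `w`, which caps the achievable background mass near 50%; the
  default background jump weight 0.85 realizes ~45–50% background
  coverage, and the sparse per-state activity keeps genome-wide
  presence near 15% of (bin, track) cells — matching real call rates,
  and keeping the Poisson background threshold well below the signal
  distribution;
- **active subsets are load-balanced**: every individual is active in
  exactly the same number of states (~25% of active states each), so
  per-track marginal distributions agree across individuals — the
  assumption quantile normalization itself relies on, and a reasonable
  description of comparable libraries;
- **planted effects that are meant to be *detected*** (power and
  recovery experiments) target states with a flat base emission, so
  the cross-individual emission structure of those states is the
  planted effect and nothing else. Planting a shift on top of a
  block-structured state is supported but buries the signal under the
  block variance — exactly as a real gQTL would be diluted in a
  pattern dominated by genotype-independent variation.

What the generator does **not** emulate: mappability and blacklist
artifacts, fragment-size effects, linkage disequilibrium (SNPs are
independent), population structure (genotype PCs are therefore optional
and default off), read-level data, diploid phasing, and
distance-decaying *cis* architecture beyond what is explicitly planted.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the model's own assumptions, not robustness to the
full messiness of real chromatin data.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
the full suite completes in a couple of minutes while keeping every
statistical check well-powered: genomes of 10⁴–10⁵ bins over two
chromosomes, 15–76 individuals, grids of 4–6 model sizes, 50 power
replicates, 100 family-wise-error repeats at 500 permutations, and 100
MAF-matched SNP permutations. Genome-scale runs (15M bins, k up to
100) use the same code paths; the forward–backward scans are linear in
bins × k².

## Known limitations

- Per-bin covariate correction can absorb chance covariate/subset
  correlation (see preprocessing above).
- Exact quantile-normalization idempotence requires tie-free input.
- Identical emission rows (truly duplicate states) are resolved
  arbitrarily by the tie-break; greedy state matching is undefined up
  to permutation for them, and Spearman-based matching carries no
  information for constant rows (e.g. an all-background state).
- The permutation-adjusted p has resolution 1/n_perm; the smoothed
  variant should be used when reporting floors.
- `select_model` counts significant triples; with very few SNPs the
  count curve is a step function and ties resolve to the smallest k.
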