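# Methods

## Scope and data model

`dermeval` consumes gene-level read-count matrices with a factorial
sample design (strain, sex, treatment ∈ {CTL, IMQ}, replicate), a
three-column homologene-style mouse↔human symbol table, human disease
expression signatures (per-gene log2FC, p, FDR), gene sets in GMT
form, a cell-type expression compendium, and a suprabasal-vs-basal
differentiation ranking. Everything downstream of count quantification
is in scope; read processing and alignment are not — the pipeline
starts from counts.

## Differential expression

For gene *g* and sample *i* the model is negative binomial with log
link,

    y_gi ~ NB(μ_gi, φ_g),    log μ_gi = o_i + x_iᵀ β_g,

where the offset o_i is the log *effective library size* (raw library
size × TMM factor) and the NB variance is μ + φμ². Contrasts are
likelihood-ratio tests of nested design matrices at fixed gene-wise
dispersion; with dispersion held fixed the LRT statistic equals the
drop in residual deviance, and p-values come from χ² with df equal to
the rank difference. BH adjustment is applied across tested genes.

**Detection filter.** A gene enters a contrast when, in ≥ 1 of the
contrast's samples, cpm = count·10⁶/library > 0.25 *and* the count is
≥ 1. The second clause implements "expression lower confidence bound
above zero": for count data any reasonable lower bound on expression
is positive exactly when at least one read was seen, so the raw count
is used rather than re-deriving an assembler-specific interval. cpm
uses raw (pre-TMM) library sizes; normalization enters only through
the GLM offsets, since detection precedes normalization in the
workflow.

**TMM.** The reference sample is the one whose upper-quartile cpm is
closest to the mean upper-quartile (ties to the first sample). For
each sample, M (log-ratio) and A (log-abundance) values versus the
reference are computed over genes nonzero in both; the M values are
trimmed 30% and the A values 5% from each tail; the survivors'
precision-weighted mean (delta-method weights) gives the log2 factor.
Factors are rescaled to geometric mean 1. These are the cited method's
published trim fractions.

**Dispersion.** With n = 2 replicates per group, gene-wise dispersion
is unidentifiable without information sharing. The Cox–Reid adjusted
profile likelihood APL_g(φ) = ℓ_g(β̂(φ); φ) − ½ log det(XᵀWX) is
evaluated on a fixed 30-point geometric grid (10⁻⁵–20). The
mean–dispersion trend maximizes, per gene, a moving average of the APL
curves of the ~10% of genes nearest in average log-cpm; the gene-wise
estimate maximizes APL_g + (prior_df/df_resid) · (local mean APL),
i.e. weighted-likelihood empirical Bayes with **prior_df = 10**
(configurable). Grid argmaxes are refined by quadratic interpolation
in log φ. A method-of-moments trend smoothed by robust lowess was
tried first and under-estimated φ by ~35% at these group sizes, which
inflated the empirical FDR; the APL scheme is both closer to the
standard estimator family for this model and calibrated (null
p-values uniform to KS ≈ 0.03 at 2000 genes, empirical FDR ≈ 0.13 at
a BH threshold of 0.10 in the validation runs).

**Fitting.** β is estimated by IRLS, vectorized across genes: the
per-gene normal equations are assembled with einsum and solved as a
batched p×p system (p ≤ 4), iterating to relative deviance change
< 10⁻⁸ or 50 iterations; unconverged genes are excluded from testing
with a logged count. Linear predictors are clipped at ±30 for
numerical safety.

**Reported fold changes.** The test statistic is never penalized, but
the *reported* log2FC comes from a refit with a small library-scaled
prior count (0.125 per sample) added, so groups with zero counts give
large finite fold changes instead of ±∞. At mean count 100 the induced
bias is < 0.01 log2 units; the planted-effect recovery experiment
(log2FC = 2 at mean count 100, φ = 0.1, 500 planted genes among 4500
nulls) measures |mean bias| ≈ 0.1, most of it the TMM composition
effect of 10% unidirectional DE rather than estimator bias proper.

**DEG calling** uses strict inequalities — FC > 2.0 or FC < 0.5, both
with FDR < 0.10 — so boundary genes are excluded. The sex × treatment
interaction test compares sex + treatment + sex:treatment against
sex + treatment within one strain, flagging genes at FDR < 0.10.

**Known limitation.** The LRT with plug-in shrunken dispersion at
n = 2/group is mildly anti-conservative (empirical FDR ≈ 0.13 at
nominal 0.10); quasi-likelihood F-tests would tighten this but are out
of scope. Fold-change estimates are *not* invariant to rescaling a
single sample's counts and library (rescaling reweights replicates in
the score equations); they are invariant to uniform depth scaling of
the whole matrix, which is the version the tests assert.

## Homology mapping

Symbols are canonicalized on load (mouse Title-case, human upper-case)
and matched case-sensitively afterwards. Any homologene id linked to
multiple mouse or human symbols, or any symbol appearing under
multiple ids, disqualifies *all* rows involved — no best-hit
resolution — so the retained map is strictly 1:1 and reproducible
under row permutation. The drop-all rule is a design choice: the
source maps are described only as uniquely associated pairs, and
dropping is the only resolution that introduces no arbitrary
preference.

## Disease match scores

Signatures are homology-joined to mouse symbols *before* ranking, so
each direction contributes exactly n = 200 mouse-measurable genes
(fewer, with a warning, when the join is smaller). "Most strongly
increased" means largest log2FC among genes with signature FDR < 0.05,
falling back to the unrestricted ranking when fewer than n qualify;
ties break by smaller p, then symbol. Undetected mouse homologs count
as fold change 1 (no response) rather than being dropped, keeping the
n-gene denominator stable; a flag drops them instead.

The score averages the up-component (mean mouse FC over
disease-increased genes) and down-component (mean reciprocal FC over
disease-decreased genes). On the ratio scale the null response scores
exactly 1; a log2 variant (up-component = mean log2FC, down = mean
negated log2FC, null = 0) is provided because ratio-scale means are
dominated by single extreme fold-change estimates at n = 2 — the
monotonicity validation uses the log2 scale for that reason. Disease
ranking aggregates by unweighted mean over a disease's signatures and
over strain–sex groups (the collapse rule across multiple signatures
per disease is not externally fixed; the unweighted mean is the
package's choice). Correlation-based concordance reports both Pearson
and Spearman, since either convention appears in published tables.

## Gene-set statistics

Rank-sum tests use mid-ranks for ties, exact enumeration when both
sides have ≤ 50 observations and no ties, and the continuity-corrected
normal approximation otherwise; the all-tied degenerate case returns
p = 0.5 one-sided / 1.0 two-sided. Cell-type signatures are the top-k
(k = 100) genes by one-sided specificity p (target population vs all
other samples), ties by larger mean difference then symbol — a
reconstruction of the usual sorted-cell signature derivation, adopted
because per-gene Wilcoxon specificity p-values are the published
selection statistic for such panels. The shift test compares set
members' log2FCs against all detected non-members (a
detection-conditional background, not the whole genome), two-sided,
with BH across all (set, group) pairs and direction called at
FDR < 0.05. ORA is the hypergeometric upper tail on
(|universe|, |term ∩ universe|, |query|, overlap) with BH across
terms.

## Positional enrichment

Genes are ranked by log2FC descending (ties by smaller p, then
symbol). Every window of w = 100 consecutive ranks (stride s,
default 1; the larger strides used in the pipeline outputs are a
runtime choice) is tested against the full ranked universe by the
hypergeometric upper tail — for a fixed window, Fisher's test on the
2×2 table gives the identical p-value, so the choice is notational.
Per-window p-values are reported unadjusted (they form a plotted
track) alongside a BH-adjusted summary. The cumulative-overlap curve
counts |top set ∩ ranking[1..i]|; its enrichment summary is the
maximum signed departure above the chance diagonal i·k/n, with a
permutation p-value from uniformly redrawn set positions (the +1/(B+1)
estimator).

## Synthetic studies

The generator emulates the target design: 7 strains × 2 sexes ×
2 treatments × 2 replicates, library sizes log-normal around 10⁶
(log-sd 0.15), baseline abundances log-normal (log2 mean 5, sd 2) so
genes straddle the detection threshold, NB counts via gamma–Poisson
with φ(μ) = 0.05 + 2/μ by default. Planted structure: a 200-gene
shared IMQ-response module (half induced at +2 log2 units, half
repressed), scaled per strain (1.5 for the B6-like strain, 0.6 for the
MOLF-like strain, 1.0 otherwise) with the last strain's males inverted
(the aberrant-responder analog); 30-gene strain-specific modules with
sign alternating across strains; and a 50-gene sex-interaction module
(+effect in females, −effect in males). Disease signatures place a
fraction c of their top genes on homologs of the shared module in the
matching direction, with top-gene |log2FC| in [1.5, 4] against noise
clipped at 1.2 so the top set is well defined even at c = 1. Cell-type
compendia plant disjoint 100-gene blocks elevated by 5 log2 units
(noise sd 0.5). The differentiation ranking plants a
suprabasal-increased set overlapping the shared induced module — the
genes the aberrant strain represses.

One RNG stream is split from the master seed per artifact class, so
adding one artifact never perturbs another's draws; fixed
(config, seed) reproduces outputs byte-identically. Ambiguous homology
decoys are emitted in mutually conflicting groups of ≥ 2 (a single
decoy cannot conflict with anything and is rejected).

What the generator does *not* emulate: batch effects, GC/length bias,
correlated genes within modules, unbalanced designs, or real
signature noise structure. Passing validation therefore establishes
internal statistical correctness (calibration, recovery, oracle
agreement, determinism), not that any particular biological conclusion
transfers to a specific dataset.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use desk-scale
problem sizes chosen to estimate each quantity stably: DE calibration
on 2200 genes × 20 seeds; estimator recovery with 500 planted genes
among 4500 nulls (planted genes kept a minority because strongly
unbalanced DE is absorbed into TMM factors by construction — a
property of composition normalization, not an implementation defect);
TMM against 50 random 2000-gene NB pairs; BH against 1000 random
vectors; match-score monotonicity over 50 seeds of a single-strain
1200-gene study; best-match recovery over 20 seeds of the full
7-strain design at 2500 genes; shift-test calibration with 1000 null
draws and 100 planted half-log2 shifts; the end-to-end run at the
default 5000 genes. All randomness derives from the run seed.
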