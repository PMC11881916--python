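# Methods

## Scope and data model

The pipeline starts from allele-assigned counts: two cells x genes integer
matrices (active-X strain, inactive-X strain) with cell metadata (barcode,
cell type, sample, age group) and gene annotation (gene id, chromosome).
Read alignment and SNP-splitting are upstream and out of scope; the input
is assumed to contain only allele-informative reads.  Bundles are stored
as Matrix Market (genes x cells on disk, orientation recorded in a comment
line and normalized on read) plus TSV sidecars; stored counts are integers
and are never mutated — all normalization produces real values downstream.

## Escape quantification

Per-cell scale factors are `target_sum / combined_total`, computed on the
summed allele matrices and applied to both, which provably preserves
within-cell allelic ratios; `target_sum` defaults to 10,000 (conventional
for droplet data; escape ratios are scale-invariant to it, and the test
suite checks this).  Normalized reads are pooled across samples within
(cell type x age), and for the combined-cell analysis by age alone.  The
wording "normalized reads" admits a cell-level or sample-level reading; the
cell-level reading is adopted here because normalization is defined per
cell everywhere else in the workflow.

For each X gene and context the escape proportion is `Xi / (Xi + Xa)`.
Mapping bias — systematic misassignment toward the better-assembled
reference genome — is estimated once globally as the autosomal
alternate/reference read ratio over all genes and all cells (the totals
carry no per-group qualification; a per-group ratio is available via the
function arguments but is not the default).  The corrected proportion is

    P_escadj = P_esc / (P_esc + r (1 - P_esc)),   r = A_Tcast / A_Tmus,

which is monotone in `P_esc` and antitone in `r` (property-tested).  The
99% interval is the Wald form with the multiplier 2.575 exactly as the
analysis defines it (not the rounder 2.5758), with `Xi + Xa` the
normalized total, for consistency with the proportion's inputs.  Bounds
are clamped to [0, 1] for reporting; classification is unaffected because
the escapee rule tests the lower bound strictly against 0.

Depth filtering uses the 5th percentile (linear interpolation between
order statistics; the method is configurable since none is prescribed) of
the pooled per-(gene, allele, group) X-linked read-sum distribution of the
table being called.  The pooling choice over (gene x allele x cell type x
age) is one of several defensible readings of "X allelic reads in all cell
types" and is isolated in one function.  Because the threshold is
recomputed from the same scaled distribution, escape status is invariant
to rescaling all normalized reads.  Ties at the threshold pass ("lower
than" is strict).  Status logic, in order: no reads at all -> not
detected; Xa below threshold -> not assessable (age trends are not
calculated, and this never silently degrades to inactive); CI lower bound
> 0 AND corrected proportion > 0.05 AND both alleles at depth -> escapee;
otherwise inactive.  Both escapee thresholds are strict inequalities.

## Transitions and Xi-only summaries

Young/old call pairs per (gene, cell type) classify as: not assessable if
either call is not assessable or not detected; increased if both are
escapees and the old CI lower bound strictly exceeds the young CI upper
bound (CI separation alone never suffices — escapee status at both ages is
required); maintained if both are escapees otherwise; lost (escapee ->
inactive); new escape (inactive -> escapee); else inactive at both ages.
The classifier is verified against a brute-force truth table over all
status pairs and CI orderings.  Sankey summaries count categories per cell
type and satisfy a conservation invariant (counts sum to the X genes
considered).  A gene is "detected" in a context when `Xi + Xa > 0` at
either age — the weakest reading, and configurable.

Cross-cell-type patterns call a gene `consistent:<category>` when all
informative categories (increased/maintained/lost/new escape) agree and
`mixed` when at least two distinct informative categories occur.
Dot-plot statistics per (gene, cell type, age) are the fraction of cells
with a nonzero inactive-strain count and the mean over all group cells of
`log1p(normalized Xi count)`; the log1p-of-normalized mean is this
package's concrete choice for the "expression" encoding, which is not
numerically pinned down elsewhere.  Escape changes per category are tested
with a paired two-tailed t test on (young, old) corrected escape values;
fewer than two pairs or zero-variance differences raise a degenerate-test
signal rather than returning a number.

## Differential expression

DE runs on raw integer pseudobulks per (cell type x sample) — count
models need integers — with features at the (gene x allele) level
uniformly, matching the allele-resolved design (this doubles the features
and is also applied to autosomes).  The depth filter retains a feature
when its total across samples is at least 10 AND at least one individual
sample reaches 10.  The filter sentence it implements is ambiguous between
"some sample" and "every sample"; the adopted reading keeps both clauses
active and monotone in counts, and the alternative is available as an
argument.

The engine is a bespoke vectorized negative-binomial GLM:
median-of-ratios size factors over features positive in all samples
(fallback: library totals scaled to unit geometric mean); gene-wise
method-of-moments dispersion estimated within age groups on
size-factor-normalized counts, floored at 1e-8; per-feature IRLS for
`log mu = log s_j + b0 + b1 * old_j` with the design shared across
features (batched 2x2 solves); Wald z on `b1` with a two-sided normal p;
Benjamini-Hochberg adjustment over the features tested within one
cell-type analysis (not globally).  Numerical parity with any published
fitter is a non-goal; the test suite cross-checks fold-change direction
and strong-effect significance against pyDESeq2 and verifies type-I
behavior and four-fold recovery by simulation.  Significance uses strict
thresholds: adjusted p < 0.05 and log2FC > 0.1 or < -0.1.

Chromosome enrichment is a Pearson chi-square (1 df, no continuity
correction — the common default for large counts, configurable) on the
2x2 table of significant vs non-significant features on the X vs a
comparison set (all autosomes, or one named autosome for size-matched
comparisons).  X-linked DEG categories evaluate in order: neuronal
(significant in >= 2 of the neuronal cell types and <= 1 glial), glial
(>= 2 glial, <= 1 neuronal), multiple (>= 2 cell types; conflicting
directions exclude the gene as discordant), else cell-type specific.  The
default cell-class map covers CA1, CA3, DG, undefined glutamatergic and
GABAergic neurons and astrocyte, microglia, oligodendrocyte and OPC glia.

## Synthetic data

The generator emulates the F1-hybrid nonrandom-XCI experiment.  Per
(cell type, age, sample) block: gene rates are log-normal (sigma 1.2)
with log-normal per-cell-type factors (sigma 0.3), scaled so each cell
type's expected depth is `mean_depth_per_cell`; per-cell library factors
are log-normal (sigma 0.25), keeping pseudobulk normalization nontrivial;
totals are gamma-Poisson (negative binomial, dispersion 0.2); informative
reads are binomial with probability 0.6 (with strain SNPs roughly every
264 bp and 150-bp paired-end reads, a bit over half of reads are expected
to overlap one); read origin is binomial with alternate-strain probability
0.5 on autosomes and the gene's escape probability on the X; mapping bias
flips alternate-origin reads to the reference with probability 0.12,
one-directional because the reported bias favors the reference genome.
The observed alternate fraction under flip bias `b` is `p(1 - b)` (the
nominal closed form `p(1-b)/[p(1-b) + (1-p) + pb]` has denominator
identically 1; the tests verify this by enumeration), so the expected
autosomal reference share is `0.5 (1 + b) = 0.56`, matching the observed
56/44 split, and the expected bias ratio is `(1-b)/(1+b) ~ 0.786`.

Default study conditions: 6 cell types (3 neuronal, 3 glial), 4 samples
per age, 170 cells per type per sample (~8,160 cells), 1,800 autosomal +
200 X genes, 5,000 reads per cell, baseline escape fraction 0.05 (within
the 3-7% escape estimate for mouse) with escape levels uniform on
[0.10, 0.40].  Planted aging effects: 6 new-escape genes (old escape
0.25), 3 lost-escape, 2 increased-escape (+0.2), 2 Xi four-fold increases
and 10 Xa four-fold changes (6 up, 4 down), applied in all cell types.
Genes named in effects get their baseline rate floored at the 75th
percentile of simulated rates, so recovery tests measure the statistics
rather than the detection limit.  All randomness flows from one seed;
identical configs give byte-identical bundles.

What the generator does **not** model: per-gene SNP density (one global
informative-read probability instead), reverse mapping bias
(reference-to-alternate flips never occur, so truly silent X genes
receive exactly zero Xi reads and the false-escape test is easier than on
real data), doublets, ambient RNA, batch effects, and per-sample random
effects (samples within an age are exchangeable, making pseudobulk
replicates less variable than real biological replicates).  Passing
recovery tests therefore demonstrates correctness of the estimators and
rules under the stated generative model, not performance on real tissue.

## Numerical and engineering choices

Wald intervals at proportions near 0 collapse to zero width (`p = 0` gives
(0, 0)); the escape rule's strict `> 0` bound then correctly refuses
escapee status.  IRLS betas are clipped to |beta| <= 30 and a 1e-10 ridge
stabilizes the 2x2 solves for features with an all-zero group; such
features end with large standard errors and p near 1.  Group keys are
sorted lexicographically everywhere, TSVs are written with a fixed float
format, and the paired bootstrap of stages (simulate -> pseudobulk ->
escape -> transitions -> DE -> enrichment) is deterministic per seed, so
reruns are byte-identical — the pipeline test compares files byte for
byte.  Problem sizes in the test suite (down-scaled cell counts for unit
tests, the full ~8k-cell default for recovery checks, 10,000 Monte-Carlo
replicates for interval coverage) were chosen to make each statistical
check well-powered at desk scale.

## Known limitations

The global bias ratio assumes mapping bias is uniform across genes;
per-gene bias would need SNP-level data that the count matrices do not
carry.  The Wald interval is anti-conservative at extreme proportions and
small depths — the depth filter mitigates but does not remove this.  The
method-of-moments dispersion with 4 samples per group is noisy, which
makes the raw Wald p values run slightly liberal at small n (the test
suite budgets for this); with planted four-fold effects at realistic
depths this does not affect recovery.  `increased_escape` magnitudes are
additive on the escape probability and capped at 0.95.
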