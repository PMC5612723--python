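# Methods

## The diversity score

The unit of analysis is a gene in a species, described by three annotation
counts: within-species paralogues *P* (the gene itself excluded, so singleton
genes have P = 0), protein-coding isoforms *I* ≥ 1, and annotated
domains/motifs *M_i* ≥ 0 per isoform (Prosite-profile style). The functional
diversity score combines them multiplicatively on a log2 scale,

    D_F = log2 P + log2 I + sum_i log2 M_i,

so one unit of D_F is one doubling of annotated functional capacity, and
heavy-tailed counts (zinc-finger paralogue expansions, domain repeats) stay
in the analysis without dominating it.

**Zero handling.** log2 of a zero count is undefined, but P = 0 and M_i = 0
are legitimate annotations. The default floors every count at 1 before the
transform (`floor` mode), so zero counts contribute 0 and no gene is dropped;
this is the minimal convention that makes D_F total. An `add-one` mode
(log2(x + 1)) is provided for users who want the transform strictly
increasing at 0; it shifts every score upward and is not the default because
it changes the value of the already-well-defined counts (log2(1 + 1) = 1 for
a single isoform). Whether a paralogue count should be used as extracted or
incremented by one (counting the gene itself) cannot be decided from score
tables alone; the package uses the count as extracted, and the `add-one`
mode covers the alternative reading.

Only protein-coding isoforms enter I and the M sum. The annotation reader
expects pre-filtered input but honours a `protein_coding` boolean column when
present, dropping flagged-out rows before grouping.

## Selection by correlation with cell-type number

Organismal complexity is proxied by the cell-type number C_s of each species
(29 for *C. elegans* up to 171 for macaque and human; the primate tie is
legal for a Pearson correlation and needs no special handling). For each
orthologue group — all one-to-one orthologues of a human gene, indexed by
the human symbol — the per-species D_F values are paired with C_s and the
sample Pearson correlation r is computed over the species that actually have
a one-to-one record; absent species are omitted, never imputed.

Groups are stratified by the earliest species carrying the gene: worm-first
(a one-to-one *C. elegans* orthologue exists), else fly-first, else
vertebrate-only (all six vertebrates present, and the correlation vector is
restricted to exactly those six). Genes first seen in *C. intestinalis* are
excluded by default; a `ciona_cohort` flag routes them into a seven-species
cohort instead. One-to-one orthology is required uniformly across cohorts.
Selection requires n ≥ 6 paired observations (four degrees of freedom).

The boundary is the two-tailed critical value of the correlation
coefficient at level alpha = 0.05,

    r_crit(n) = t_c / sqrt(t_c^2 + (n - 2)),

with t_c the two-tailed alpha quantile of Student's t on n − 2 degrees of
freedom (0.6664, 0.7067, 0.7545, 0.8114 for n = 9, 8, 7, 6; the test suite
cross-checks these against bisection on the exact null density of r). A gene
is selected when r > r_crit strictly — the comparison always uses the
unrounded boundary; the 2-dp values in the cohort summary table are
presentational only. Because the boundary is two-tailed but only positive
correlations are kept, the expected null selection rate is alpha/2 = 2.5%.
No multiple-testing correction is applied across genes at this stage, by
design: the selection is a screen, not a hypothesis-level inference, and
downstream stages operate on the screened set.

Degenerate inputs are excluded, not fatal: a constant D_F vector (undefined
correlation) or a missing score for a contributing species excludes that
gene with a logged reason.

## Term enrichment

Each term defines a 2×2 table over the N input genes (K with the term) and
the n selected genes (k with the term). Fold enrichment is (k/n)/(K/N);
significance is the exact hypergeometric tail — upper for
over-representation, lower for depletion — with no normal approximation
(the suite checks every table with N ≤ 12 against full enumeration of
C(N, n) draws). A term is flagged enriched iff fold > 2.5 and p < 0.05
(both strict, so fold = 2.5 exactly is not flagged) and depleted iff
fold < 1 and the lower tail is below alpha. Raw p-values are the default;
Benjamini–Hochberg adjustment is available behind an `fdr` flag. Terms are
flat labels: any term-hierarchy propagation must be done upstream. The
non-redundant union of selected genes across flagged terms is reported with
per-term membership for Venn-style accounting.

## Interaction networks

The edge list mirrors a STRING export restricted to one evidence channel:
gene pairs with a confidence score in [0, 1]. Edges are kept when the score
is ≥ 0.700 (inclusive, the conventional high-confidence level) and both
endpoints are selected genes; self-loops are dropped and duplicate pairs
keep the maximum score. Connected components with ≥ 3 genes are reported in
descending size (ties broken by lexicographically smallest member), plus a
degree table in descending degree. The component-size threshold is
configurable because "at least three" and "more than three" are both
defensible readings of the convention; 3 is the default.

## The synthetic generator

The generator emulates what a database extraction would produce, with known
ground truth. Its defaults are the study conditions used throughout the
tests and the acceptance script: 2,000 input genes, 10% carrying signal at
target correlation rho = 0.9, cohort mix 50% worm-first / 25% fly-first /
25% vertebrate-only (matching the stratum proportions of the real
selection), 10% per-species orthologue dropout respecting each cohort's
minimum of six, four planted enriched terms (signal fractions 0.5–0.8,
background rates 0.02–0.05) among 20 terms total, and planted interaction
cliques of 44, 8 and 6 genes mirroring a large repressive-complex module,
a Mediator-sized module and a remodelling-complex module.

**Latent model.** Per gene and species, a latent log2 diversity target is
drawn as d*_s = mu + b·(z_s − z̄) + eps, with z_s the standardised log
cell-type number (log spacing stops the two primates from dominating
leverage), eps ~ N(0, sigma²), mu = 10 and sigma = 1.5 — chosen once to give
realistic D_F ranges (a handful of paralogues, several isoforms, a few
domains each at the human end; sparse annotations at the worm end) while
keeping signal genes clear of the zero clamp. For signal genes the slope is
calibrated per gene,

    b = sqrt(sigma^2 + 1/12) · rho / (sqrt(1 − rho^2) · sd(z over the gene's species)),

so that rho refers to the realised (C_s, D_F) pairs of the species the gene
actually has: a vertebrate-only gene sees a far narrower complexity spread
than a worm-to-human gene and needs a steeper slope, and the 1/12 term
accounts for the variance of the count-realisation error below. Null genes
have b = 0.

**Count realisation.** The latent budget is turned into integers by picking
the isoform count first (nearest integer in log2 to its 45% share, capped at
40), then the paralogue count from its share of the remainder, then
spreading the motif budget greedily across isoforms so rounding errors
cancel; each choice takes the integer whose log2 is nearest the remaining
per-slot target. The realised D_F is provably within one log2 unit of the
target (the residual error is a single final rounding, at most log2(1.5) ≈
0.585), and non-positive targets clamp to the all-ones record. Realisation
error behaves approximately as Uniform(−½, ½), hence the 1/12 variance
correction above.

**What the generator does not model.** Counts are order-of-magnitude
plausible, not matched to real Ensembl marginal distributions; species are
independent observations with no phylogenetically correlated noise (the
selection statistic treats them the same way); annotation depth is uniform
across species, whereas real invertebrate genomes are systematically
under-annotated; and noise interaction edges are always sub-threshold, so
edge noise stresses only the filter, not the component structure. Passing
tests therefore validate the pipeline's statistical behaviour under its own
assumptions, not the biological conclusions one would draw from real data.

## Numerical and design choices

- Pearson r is computed from the centred product-moment definition and
  clipped to [−1, 1] against floating-point overshoot.
- The t quantile comes from scipy; the critical-value test cross-checks it
  by bisecting the integral of the exact null density (1 − r²)^((df−2)/2).
- Hypergeometric tails use scipy's exact distribution functions; the
  independent test oracle enumerates draws combinatorially.
- TSV numeric round-tripping is fixed at 6 decimal places.
- Reading an annotation table is row-order invariant: rows are grouped by
  (species, gene) and isoforms sorted by identifier.
- Cohort summaries round r_crit to 2 dp for display; selection never uses
  the rounded value.

## Problem sizes

The test suite runs the null calibration at 10,000 genes, the
signal-recovery condition at the default 2,000, generator distribution
checks at 300–3,000, and enumeration oracles at N ≤ 12; the whole suite
completes in well under a minute, and the acceptance script in under a
minute, on a single CPU.

## Known limitations

- Cell-type numbers are a coarse, partly historical complexity proxy, and
  two species share the value 171; the pipeline treats them as given.
- The selection applies no phylogenetic correction: closely related species
  contribute as independent observations.
- The critical-value table and the strict-inequality rule assume bivariate
  normality of (C, D_F) under the null; D_F is discrete, which for realistic
  score ranges shifts the null selection rate by well under a percentage
  point (the calibration test bounds it).
- Enrichment treats annotation terms as flat labels; hierarchy-aware
  analyses must propagate annotations before input.
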