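# Methods

## Differential expression on response ratios

Input is a genes × samples RPKM table with two conditions (−Fe, +Fe)
and equal replicate counts, replicates paired by index. For gene *g*
and replicate *i* the response ratio is

    ratio_i = (rpkm_minusFe_i + c) / (rpkm_plusFe_i + c)

with pseudocount *c* = 0.01 RPKM by default (prevents division blow-ups
at weakly expressed genes; set to 0 for noise-free fixtures). The
reported summary is the arithmetic mean of the per-replicate ratios and
their sample SD (*n*−1 denominator) — deliberately the mean of ratios,
not the ratio of means, matching how per-replicate ratios are usually
tabulated alongside their mean.

Significance comes from a two-sample, equal-variance Student t-test on
log₂(rpkm + c), the standard symmetric treatment of induction and
repression at 3-vs-3 replicates. A paired one-sample alternative on the
log ratios is selectable (`DEFilterConfig.test="one_sample"`); with
only the test named and no variant stated in common usage, the
two-sample form is the default and the choice is exposed rather than
hidden. Genes with zero variance on both sides produce a t statistic of
0/0; their p-value is defined as 1 (no evidence), never NaN.

The fold-change filter takes the mean ratio: up if ≥ FC, down if
≤ 1/FC, at *p* ≤ alpha (0.05). The reciprocal down-cutoff makes the
filter symmetric on the log scale, and implies the nesting property
DE(1.5) ⊆ DE(1.2) that the property tests assert. No multiple-testing
correction is applied at this stage; the analysis convention is raw
per-gene p-values with the fold-change filter carrying most of the
specificity.

Records transcribed from printed tables carry mean/SD only; their
p-value is stored as the sentinel 0.0 because printed rows were already
pre-filtered at *p* < 0.05 and replicate-level data for them are not
available.

## Co-expression network and modules

Pairwise Pearson correlation is computed over all compendium arrays
with the standard product-moment formula (`numpy.corrcoef`; an
independent longhand implementation serves as the test oracle at
1e−12). Edges require **signed** r ≥ 0.7: co-expression here means
positive covariation, and strong anticorrelation does not join genes
into a module (an `use_abs` flag admits it when wanted). Genes with
zero variance across arrays have undefined correlations; these are
stored as missing and can never pass the threshold.

A module is exactly a connected component (≥ 2 nodes) of the
thresholded graph — by construction it has no edges to any other
component. Modules are named M1, M2, … in decreasing size with ties
broken by the lexicographically smallest member, so output order is
deterministic.

The bait–prey construction thresholds correlations over baits ∪ preys,
removes every prey–prey edge, then removes all degree-0 nodes. Bait–bait
edges are retained (only two-prey edges are excluded), and a bait left
isolated after filtering is dropped too — a node qualifies by being
linked to a bait by at least one edge, and an isolated bait has none.

## GO enrichment: classic and elim

Annotations are closed under is_a ancestry before testing (true-path
rule). For a term with `pop_count` annotated genes in a universe of
`pop_total`, and `study_count` of the `study_total` study genes
annotated, the classic p-value is the hypergeometric upper tail
P(X ≥ study_count). The universe is a gene list, not an annotation
list: it may contain genes with no GO annotation, which simply never
count for any term. By default the universe is all annotated genes in
the supplied annotation file; it is configurable.

The elim procedure processes terms level by level, deepest first, where
a term's level is the **longest** path to a root (shortest-path leveling
is available as an option). Each term is tested on its current gene
sets — propagated annotations minus genes already eliminated for it —
and when its p-value is strictly below alpha (0.01 default), its
current genes are marked eliminated for every strict ancestor. Elim
p-values can move in either direction relative to classic, so no
ordering between the two is asserted; both are reported. With alpha = 0
elimination never triggers and elim reduces exactly to classic, which
the tests exploit as an identity check. Term p-values are not corrected
for multiple testing: the elimination itself is conservative, and
reported significance is the raw p < 0.01 convention.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their configs (seeds are mandatory
fields, not global state), and every dataset ships its ground truth.

**−Fe/+Fe table.** Gene baselines b_g ~ N(5, 2²) on the log₂ RPKM
scale; planted effects ±m log₂ units (default m = 1; the power analyses
use m = 2); i.i.d. cell noise ε ~ N(0, 0.25²); values are 2^(b+δ+ε), so
RPKM positivity is automatic and ratio statistics are tractable. Three
replicates per condition by default, matching the three-biological-
repeat design the ratio statistics assume. Not modelled: count-level
(negative binomial) noise, library-size effects, outlier replicates.

**Compendium.** 300 arrays by default, the scale of the curated root
compendium the network analysis is designed around. Each planted module
is a single-factor equicorrelated block, x_ga = √v·z_a + √(1−v)·ε_ga,
giving population pairwise correlation exactly v (default 0.85) — an
analytic handle that makes behaviour at the 0.7 cutoff predictable: at
n = 300 the sampling SD of r around 0.85 is ≈ 0.02, so planted edges
essentially never miss, while the null tail P(|r| ≥ 0.7) is ≈ 1e−38,
so background genes essentially never connect. No between-module
correlation is planted, consistent with modules being disconnected by
definition. Not modelled: batch effects, overlapping modules, missing
values.

**GO world.** A complete b-ary is_a tree (depth 3, branching 2 by
default), genes annotated uniformly to leaves, and a study set drawn
with over-sampling odds (default 10×) on genes of the planted leaves.
Planted terms must be leaves so "enrichment of exactly this term, not
its ancestors" is well defined.

Passing on these worlds demonstrates correctness of the statistics and
the graph/ontology algorithms under the stated generative assumptions;
it does not certify performance on real arrays or real GO annotation
releases, where correlation structure is not block-equicorrelated and
annotations are neither uniform nor leaf-only.

## Pipeline and determinism

`run_pipeline` chains DE (at FC 1.2 and 1.5), the network + modules over
the strict DE set, the bait–prey network (baits = DE kinases/
phosphatases, preys = remaining DE genes), and per-module elim
enrichment, writing all outputs plus a manifest of per-stage counts and
wall-clock times. Identical config + seed reproduces identical counts;
the committed golden manifest (seed 20130603, 1000 genes, 300 arrays)
pins the end-to-end behaviour. The analysis scripts and the acceptance
script use these same problem sizes — 1000 genes, 300 arrays, 20
compendium seeds, 1000 null GO worlds — chosen so each property is
measured with comfortable margin while a full run stays interactive.

## Numerical and degenerate-input choices

- Gene IDs are upper-cased on ingestion and compared case-insensitively
  (AGI codes appear as both `At2g46700` and `AT2G46700` in the wild);
  undirected edges are canonicalized as (min, max) pairs.
- Edge weights are written with 6 significant digits; round-trips are
  asserted at that precision.
- An empty graph yields an empty module list; an empty study set skips
  enrichment; a config error is raised before any sampling.
- The within-correlation 1 is excluded from configs but 1 − 1e−12 is
  accepted as a limiting value for degenerate-limit tests.

## Known limitations

- The real study's compendium-scale numbers (87-node/248-edge network,
  the FEPKPP1–3 module compositions) depend on external array data and
  a historical GO release; they are context, not targets, and the
  package validates the machinery on planted synthetic data instead.
- The elim implementation covers the is_a hierarchy only (no part_of or
  other relations), matching the OBO-lite format it consumes.
- Correlation uses complete rows; there is no pairwise-deletion support
  for missing array values, since inputs are validated dense.
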