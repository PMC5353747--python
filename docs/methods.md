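# Methods

## Problem and model

`sigoverlap` quantifies whether the transcriptome of a diseased adult
tissue resembles the immature transcriptome of the same tissue — the
"pseudo-immaturity" (dematuration) question. The unit of analysis is the
*gene signature* (a "bioset"): the ordered set of genes passing a
fold-change and t-test filter in a two-group comparison, each annotated
with its direction of change. Two signatures — e.g. patient-vs-control and
infant-vs-adult — are compared with a rank-based overlap statistic, the
overlap is decomposed by direction of change, genes concordant in both
comparisons form a *concordant bioset*, and that bioset is partitioned
across cell-type developmental signatures to attribute the effect.

## Differential-expression signatures

For each feature, the group means of log2 intensity are differenced and
reported as a signed linear fold change: `r = 2^(m_num − m_den)` for
`r ≥ 1`, `−1/r` otherwise, so `|FC| ≥ 1` and the sign encodes direction
(numerator group = patient or infant). Significance uses Welch's
unequal-variance two-sided t-test; the pooled-variance variant would also
be defensible, but Welch is the safer default when group variances differ,
which is typical of post-mortem cohorts. A feature enters the signature
iff `|FC| > fc_threshold` *and* `p < p_threshold`, both strict. Defaults
are 1.2 and 0.05 — the conventional lowest-sensitivity thresholds for
commercial microarray platforms — and the fold-change threshold is
per-dataset configurable (e.g. 1.3 for a developmental hippocampus
series).

Signatures are ordered by ascending p, ties broken by descending |FC|,
then lexicographic gene id. The rank-scanning test below needs *some*
deterministic ordering; this rule makes reruns and cross-machine results
identical. Probe-level data are collapsed to genes by keeping, per gene,
the probe with the smallest p (ties: largest |FC|, then lexicographic
probe id); unmapped probes are dropped. Gene identifiers are uppercased
and stripped for cross-dataset joins.

Degenerate inputs: identical constant groups give p = 1 (never
significant) rather than an error, so synthetic edge cases flow through;
constant groups with different values give the smallest positive double,
keeping p in (0, 1]. A fold change of exactly ±1.0 (possible when the
mean difference underflows) has no direction and never passes a strict
threshold ≥ 1.

## Ortholog mapping and the universe

Cross-species comparisons translate the reference signature into the
query species' id space through a two-column ortholog table. One-to-many
orthologs fan out (each target inherits the source's FC and p);
many-to-one collisions keep the entry with the smallest p — preserving
signal without double-counting a target gene — and the mapped signature
is re-ranked by the standard rule.

The background *universe* of every hypergeometric test is the set of
query-space genes with at least one ortholog measured on the reference
platform (plain intersection for same-species comparisons). The
contribution analysis reuses the same platform background. This
"orthologue-mapped intersection" is the defensible default — every gene in
it could in principle appear in both signatures — and the universe is an
explicit object, so a union or fixed-N background can be substituted.

## The running Fisher test

Given two ranked signatures inside a universe of size N, the test scans
matched fractional prefixes: at fraction `f` the prefix pair is
`(⌈f·n_query⌉, ⌈f·n_reference⌉)`. The default scheme takes `f` at the
deciles of the shorter signature (10 cutoff pairs; every rank when the
shorter signature has fewer than 10 entries); a `per-rank` scheme scans
one fraction per rank of the shorter list. At each cutoff pair the
one-sided hypergeometric enrichment tail `P(X ≥ k)` of the prefix overlap
`k` is computed exactly (`scipy.stats.hypergeom.sf`). The summary is

    p_final = min(1, min_c p_c × n_cutoffs)

— the best tail over the scan with a Bonferroni-style correction by the
number of *distinct* cutoff pairs scanned (duplicate pairs from the
ceiling on short lists are deduplicated). The correction makes the scan
conservative: under independence the type-I error at nominal 0.05 is
measured at ≈ 0.01 over 1,000 replicates (the `experiments` module
recomputes this). An empty signature yields the degenerate
`p_final = 1`, overlap 0.

The scan is asymmetric in principle — swapping query and reference leaves
the overlap count unchanged but may alter `p_final` through the ceilings
in the cutoff scheme.

Directional decomposition restricts both signatures to one direction for
each of the four pairs (up,up), (down,down), (up,down), (down,up) and
runs the same scan against the *full* universe N. A common background is
used because the four sub-overlaps partition the total overlap; a
direction-restricted background would make the four sub-tests mutually
incomparable. The four sub-tests are guarded at the Bonferroni level
alpha/4 (0.0125 at alpha = 0.05); the family of dataset pairs in a study
is corrected at alpha/m with m taken from the run configuration. An
overlap is classified *positive* when concordant genes — (up,up) plus
(down,down) — outnumber discordant ones, *negative* when the reverse
holds, and *mixed* on a tie.

## Concordant biosets and cell-type contribution

The concordant bioset is the union of the (up,up) and (down,down) overlap
gene sets, each member carrying the shared direction and per-source
statistics. Against three cell-type developmental signatures the bioset is
partitioned into the eight exclusive membership regions; "specific to" a
cell type means the exclusive region (in that set and neither other), and
a cell type's *marginal* is the sum of its four covering regions.
Percentages are `100·count/bioset_size` rounded half-up to one decimal
(`decimal.Decimal`, not banker's rounding — half-up reproduces the style
of published contribution tables). Direction concordance counts shared
genes whose bioset direction equals their developmental direction.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: two
independent two-group studies over the same genes; a *shared program*
whose genes are mean-shifted in both studies, in the same direction with
probability `concordant_fraction`; per-study specific programs; and three
cell-type modules overlapping the shared program to configurable degrees
(FS neurons largest by default, so the planted dominant contributor is
recoverable). Intensities are independent normals on the log2 scale —
per-gene baseline N(8, 1) per study plus N(0, 0.2) within-group noise —
because the analysis consumes only group means, variances and ranks.
Defaults: 10,000 genes, 10 samples per group, a 100-gene shared program
at 1.5 log2 units, 50-gene specific programs. Under these conditions
signatures hold ≈ 180 genes (the planted 150 plus a few dozen false
positives from the joint filter) and the planted program is recovered
essentially completely.

Deliberately not modelled: probe-level artifacts, batch effects,
correlated genes, heavy-tailed noise, and post-mortem covariates (age,
PMI, pH). Passing tests therefore demonstrate the statistical machinery
under the stated noise model, not robustness to those real-data features.
All draws come from a single seeded `numpy` generator; same-config reruns
are bit-identical, and truth records (planted memberships and directions)
are emitted alongside the data so recovery is scored without
re-inference.

## Validation experiments

`sigoverlap.experiments` packages the two standing simulations:

* **Null calibration** — 1,000 pairs of independent random 100-gene
  signatures in a 2,000-gene universe; the fraction rejected at nominal
  0.05 must stay ≤ 0.07.
* **Planted recovery** — 200 independently seeded paired studies at the
  default conditions; detection at `p_final < 10⁻³`, ≥ 80%
  direction-correct bioset recall and a positive classification are each
  required in ≥ 95% of replicates.

These sizes keep the full suite and the reproduction script to well under
a minute of simulation time while leaving the binomial noise on the
measured rates small against their margins.

## Numerical choices and limitations

* Hypergeometric tails are exact (scipy); results are clamped to
  `(0, 1]` — the lower clamp at the smallest positive double only matters
  at astronomically significant overlaps.
* GCT/TSV readers parse floats with correct rounding
  (`float_precision="round_trip"`), and writers emit `repr` of doubles,
  so write-read round trips are bit-exact.
* Report JSON is written with sorted keys; identical inputs give
  byte-identical reports.
* The published absolute overlap p-values of the original
  correlation-engine service cannot be regenerated: its exact scan
  granularity and correction factor are proprietary and the underlying
  GEO series are not bundled. The worked-example reconstructions operate
  on the published *counts*, which are fully determined.
* The contribution stage treats cell-type signatures as opaque directed
  gene sets; differing cell-collection methods or maturation windows
  between such datasets are a scientific caveat outside the statistics.
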