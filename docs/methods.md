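# Methods

This note documents the models, parameter defaults and numerical choices
behind `traitatlas`, and what the synthetic benchmarks do and do not show
about real data.

## Trait model and module completeness

A genome is represented only by its binary trait vector.  Module-type
traits are reconstructed from KO annotations against a module definition:
an ordered list of reactions, each reaction an OR-set of alternatives,
each alternative an AND-set of KOs (multi-subunit complexes count only
when every subunit is annotated; a partially annotated complex does not
satisfy its reaction).  Completeness requires every reaction satisfied,
except that one missing reaction is tolerated in modules with at least
three reactions — a deliberate compensation for incomplete functional
annotation, which typically covers only roughly two thirds of a genome's
genes.  The strict rule (no tolerance) is available via
`strict_modules: true` for sensitivity checks.  Module definitions are
supplied as JSON in this OR-of-AND form; the full boolean definition
grammar of annotation databases (optional components, nested
parentheses) is intentionally not parsed, which keeps the package
independent of database versions at the cost of requiring pre-simplified
definitions.

## Association statistics

Trait and genome similarity is the phi coefficient.  Significance uses
the identity χ² = n·φ² with one degree of freedom and **no** continuity
correction — the correction would break the identity the test is built
on.  Multiple testing uses Benjamini–Hochberg (the standard FDR default).
For trait clustering, negative correlations are zeroed first so that
clustering is driven by positive association only, and the BH family is
by default the positively correlated pairs (pairs already zeroed by sign
are not tested); `fdr_family="all"` applies BH to every pair before sign
thresholding, for users who prefer the larger family.  Degenerate pairs
(a constant margin) get φ = 0, p = 1.  Constant genomes or traits are
dropped with a warning rather than imputed, since phi is undefined for
them.  Genome similarities are never thresholded: negative genome pairs
are legal, passed through, and counted in the provenance record (on real
collections that share core metabolism they are rare, but the
implementation does not assume this).

## Affinity propagation

Exemplar clustering uses damped responsibility/availability message
passing.  Defaults: damping 0.9, at most 1000 iterations, convergence
declared when the exemplar set is stable for 100 consecutive iterations —
the defaults of the widely used R implementation of the algorithm.  The
preference (diagonal) is the q-quantile of the off-diagonal similarities
(linear interpolation), q = 0.5 by default; larger q yields more, smaller
q fewer clusters.  Determinism: instead of unseeded noise, exact
degeneracies are broken by a seeded symmetric jitter of relative
magnitude `ap_jitter_scale` (default 1e-9), and assignment ties break
toward the lowest item index, so identical inputs and seeds give
identical clusterings.  After convergence, exemplars are refined once by
maximizing within-cluster similarity.  Non-convergence returns the
current solution flagged `converged=False` rather than failing.
`brute_force_exemplars` maximizes the same net-similarity objective
exactly over all exemplar subsets (n ≤ 10) and serves as the test oracle;
`agglomerate_exemplars` greedily merges clusters by the best joint-exemplar
mean similarity, for dendrogram export.

## Interpretation rules

* **Coherence** (default rank: genus, configurable): monophyletic = the
  cluster contains all and only genomes of one taxon; paraphyletic =
  exactly one taxon, part of it elsewhere; polyphyletic = several taxa.
* **LTC presence** uses strict majorities: present in a genome when
  *more than* half the member traits are present, present in a cluster of
  genomes when present in more than half of them.  Categories partition
  on genome-presence: core > 0.9, ancillary ≤ 0.3, common between (the
  boundary values 0.9 and 0.3 therefore fall to common and ancillary
  respectively).  The mean within-LTC r is computed on raw,
  pre-thresholding phi values so it can be compared against the
  background mean over all pairs.
* **Prevalence prefilter**: a trait enters LTC clustering when
  count/n ≥ 0.03 evaluated exactly, with an absolute `prevalence_min_count`
  override for replicating count-based cutoffs.
* **Enrichment**: the interaction-trait load of a GFC is tested by
  permuting genome labels (GFC sizes preserved, default 999 permutations),
  statistic = mean flagged-trait count, empirical p with the +1 correction
  (never exactly zero), BH across GFCs.  This permutation design is this
  package's own construction for an analysis whose original test was not
  fully specified; single-genome GFCs are flagged low-power.
* **Size expectation**: interaction-trait count is regressed on genome
  size (ordinary least squares); per-taxon mean residuals get a two-sided
  permutation p by shuffling residuals across genomes.
* **Sensitivity**: clustering is re-run over a q grid (default 0.1–0.9)
  and with overrepresented taxa down-sampled to 80/60/40% of their
  genomes (without replacement, seeded), reporting cluster counts and the
  adjusted Rand index against the full-data clustering restricted to the
  retained genomes.  "Overrepresented" defaults to more than 5% of all
  genomes at the coherence rank; this threshold is a declared convention,
  configurable via `overrepresented_frac`.

## Environmental mapping

Hits are consumed as tabular alignments (headered TSV or the 12-column
outfmt-6 dialect); the alignment itself is external.  At each identity
threshold (ladder 100 / 97 / 94.5 / 86.5%, spanning strain- to
family-level resolution) the top 20 hits by bitscore are retained, and
the specificity index is the fraction of retained hits in the modal GFC.
Only index = 1 maps an OTU — with a single GFC among the hits the modal
convention coincides with "all hits agree"; the modal choice merely
defines the index for discordant OTUs, which stay unmapped.  The
synchrony comparison reports Shapiro normality per group (skipped below
3 observations), a one-sided Welch t-test as the primary result (the
direction of interest is same-GFC > different-GFC; a two-sided p is also
emitted), a Mann–Whitney rank test as a distribution-free companion, and
two randomization controls that reassign pairs to groups keeping the
observed sizes or two equal halves — each reporting the fraction of
randomizations clearing the same significance level as the main claim
and the empirical p of the observed t against the randomization null.

## Synthetic-data generator

The generator is the package's test bed and defines the benchmark
conditions.  Genomes are assigned round-robin to `n_gfc_blocks` planted
blocks and traits to `n_ltc_blocks` linkage blocks; each linkage block is
carried by a distinct set of consecutive genome blocks (one block each
for the first `n_gfc_blocks` linkage blocks, widening runs after that),
so planted trait blocks stay statistically distinguishable even when
linkage blocks outnumber genome blocks.  Presence is Bernoulli:
`block_trait_occupancy` (default 0.95) inside a carrying block,
`background_occupancy` (default 0.05) outside.  Module traits are
realized through generated definitions (3–8 reactions, two alternatives
each, 20% two-KO complexes, globally unique KOs) and per-KO independent
Bernoulli deletion at `annotation_dropout` (default 0.1) — the simplest
dropout model consistent with partial functional annotation; where
deletion leaves a planted module unreconstructible the gap is recorded in
the planted truth.  Genus labels match the planted block with probability
`taxon_concordance` (default 0.9); higher ranks group genera
deterministically.  Environmental tables plant per-OTU hit specificity
and a Gaussian same-block synchrony shift (scores are Gaussian because
the analysis applies a normality check followed by a t-test).  Defaults —
150 genomes, 300 traits, 5 genome blocks, 6 linkage blocks — are the
reference benchmark conditions used by the acceptance script and were
fixed up front.

What passing these benchmarks shows: the pipeline recovers block-style
planted structure under moderate occupancy noise and annotation dropout,
its tests are calibrated under Gaussian nulls, and its rules implement
the stated semantics exactly.  What it does not show: real genomes have
phylogenetically autocorrelated, non-block trait structure, correlated
annotation errors, unbalanced taxon sampling and non-Gaussian synchrony
scores; absolute cluster counts and percentages from real collections
depend on the annotation catalogue and are not reproduced by these
synthetic conditions.

## Problem sizes and runtime

The shipped benchmarks use 150 × 300 end-to-end runs, 200-item planted
similarity matrices, 100 brute-force comparisons at n ≤ 8, and 200
replicates for power/calibration — sizes chosen so the whole suite and
the acceptance script each run in well under a minute on a single CPU
while keeping binomial/simulation error far from the asserted margins.

## Known limitations

Auxotrophy is inferred purely from pathway/transporter presence — no
precursor salvage or pathway-gap reasoning.  Transporters are treated as
uptake systems (directionality is not predicted).  The trait catalogue
itself (which modules, metabolites and transporter families exist, and
which count as interaction traits) is an input, not something the package
derives.  Affinity propagation offers no global optimality guarantee
beyond the small-n oracle comparisons; the sensitivity analysis is the
intended tool for judging stability on real data.
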