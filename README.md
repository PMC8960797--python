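# traitatlas

Trait-based comparative genomics for bacterial genome collections.
`traitatlas` turns per-genome functional annotation tables into an atlas
of **genome functional clusters** (GFCs — groups of genomes with similar
trait repertoires), **linked trait clusters** (LTCs — traits that
co-occur across genomes more than expected by chance), B-vitamin
acquisition strategies, interaction-trait enrichment, and a mapping of
environmental 16S amplicons onto the atlas.  It is written for microbial
ecologists who want to compress hundreds of genomes into interpretable
functional units and generate testable hypotheses about microbial
interactions (vitamin exchange, siderophores, secretion systems,
phytohormones).

## The method

A *genetic trait* is a complete functional unit scored present/absent per
genome: a metabolic module reconstructed from KEGG Ortholog (KO)
annotations, a secondary-metabolite cluster, a phytohormone pathway, a
transporter, or a sulfur-catabolism pathway.  Module completeness follows
a reaction-wise rule: a module with reactions R₁…Rₙ is complete when every
reaction has at least one annotated alternative (alternatives may be
multi-subunit AND-complexes), with one missing reaction tolerated when
n ≥ 3 to absorb annotation gaps.

From the binary genomes × traits matrix **X** the pipeline computes
pairwise phi coefficients (Pearson r on dichotomous variables),

  φ = (n₁₁n₀₀ − n₁₀n₀₁) / √(n₁.n₀.n.₁n.₀),  χ² = n·φ² (df = 1),

tests each trait pair with the chi-square statistic, applies
Benjamini–Hochberg FDR, zeroes negative and non-significant trait
correlations, and feeds the resulting matrices as similarities into
**affinity propagation** (implemented here from scratch, with an exact
brute-force oracle for small instances).  The preference is the
q-quantile of the off-diagonal similarities (default q = 0.5), so the
number of clusters emerges from the data.  Genome clusters become GFCs;
trait clusters (after a ≥ 3% prevalence prefilter) become LTCs.

Interpretation then follows fixed rules: a GFC is *monophyletic* when it
contains all and only the genomes of one taxon; an LTC is present in a
genome when > 50% of its traits are present and in a GFC when present in
> 50% of its genomes, and is *core* (> 90% of genomes), *common* or
*ancillary* (≤ 30%); per-vitamin strategies are *consumer* (transport
only), *independent* (synthesis only), *flexible* (both) or *none*,
spanning a 4³ = 64-cell configuration space over B1/B7/B12.  Amplicon
OTUs map to a GFC only when all retained alignment hits (identity ≥
threshold, top 20) agree — a *specificity index* of 1 — and a one-sided
Welch t-test (with rank-test and randomization controls) asks whether
same-GFC OTU pairs are more temporally synchronous than different-GFC
pairs.

A first-class synthetic-data generator plants GFC/LTC block structure,
annotation dropout, taxon concordance and synchrony effects, so every
stage is testable against known ground truth.

## Worked example

```python
from traitatlas import PipelineConfig, SyntheticSpec, gen_dataset, run_all, write_dataset
data = gen_dataset(SyntheticSpec(n_genomes=100, n_traits=150,
                                 n_gfc_blocks=5, n_ltc_blocks=6, seed=42))
write_dataset(data, "inputs")
run_all(PipelineConfig(seed=42), "inputs", "results")
```

Running `python examples/01_simulate_and_cluster.py` (which adds the
comparison against the planted truth) prints:

```
genomes: 100, traits: 150
GFCs found: 5 (planted 5), ARI vs truth: 1.00
LTCs found: 6 (planted 6), ARI vs truth: 1.00
coherence labels: {'polyphyletic': 5}
mean phi within LTCs vs all trait pairs: 0.75 vs 0.02
```

The five planted genome blocks and six planted trait blocks are recovered
exactly (adjusted Rand index 1.0).  Traits inside a recovered LTC
correlate strongly (mean φ 0.75) against a near-zero background (0.02) —
the contrast that makes an LTC evidence of linked evolution.  The
coherence labels are polyphyletic here because the generator planted 90%
genus/block concordance; at `taxon_concordance=1.0` every GFC is
monophyletic.  The other scripts in `examples/` walk through module
completeness calls, vitamin strategies and environmental mapping.

A thin CLI wraps the same functions:

```bash
traitatlas simulate --out inputs --seed 42
traitatlas run --in inputs --out results
```

## Layout

- `src/traitatlas/` — the library: `datatypes`/`io`/`config` (data model
  and tables), `modules` (module completeness), `linkage` (phi/chi²/FDR),
  `apcluster` (affinity propagation + oracle), `profiles` (prevalence,
  vitamins, interaction counts), `interpret` (coherence, LTC semantics,
  enrichment, size expectation, sensitivity), `envmap` (OTU mapping,
  synchrony), `simulate` (synthetic data), `pipeline` (orchestration),
  `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — modelling assumptions, parameter defaults and
  numerical choices.
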