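# Methods

## Problem and approach

Bulk RNA-seq of closely related yeast strains often shows inter-replicate
biological variation large enough that pooled-replicate differential tests
(e.g. Cuffdiff run on all three replicates per condition) call nothing
significant, even when the overall transcriptome correlation between
replicates is ~0.996. `xyloseq` implements the qualitative alternative:
run a pairwise caller on **every** control-replicate × experiment-replicate
combination (9 comparisons for 3 vs 3 replicates) and keep the transcripts
that behave consistently across comparisons.

A feature is *selected at cut-off n* when a single direction (up or down)
is called significant in at least `n` of the pairwise comparisons. "Up"
always means increased in the experimental group relative to the control
group. Two readings of "consistent behavior" are supported:

* **strict** (default): all significant calls must agree in direction, and
  that direction must reach `n` — i.e. `n_up ≥ n` and `n_down = 0`, or
  vice versa;
* **relaxed** (`require_consistent_direction=False`): total significance
  count reaches `n`; the consensus direction is the majority one.

The strict reading is the default because at the strictest cut-off
(`n = 9` for 3×3 replicates) a single discordant call is direct evidence
against a consistent response. Selected sets are non-increasing in `n`
under both readings.

### Pairwise caller

The consensus logic is caller-agnostic. Two callers are provided:

* `read_cuffdiff_diff` ingests real per-pair Cuffdiff 2.x `.diff` output.
  Significance is the conjunction of the file's `significant == yes` flag
  and `p ≤ alpha` (default α = 0.05). The file format leaves open whether
  the flag, the p-value or the q-value should decide; the conjunction is
  the conservative choice and `use_q_value` switches the threshold to the
  q-value where present.
* `default_pair_caller` is an explicitly documented simplification for
  when only an FPKM matrix is available: it thresholds the
  pseudocount-shrunken fold change `log2((v_exp + ε)/(v_ctl + ε))` at
  `min_abs_log2fc` (default 1.0, ε = 1.0 FPKM). It has no error model and
  reports degenerate p-values (0/1). The pseudocount suppresses spurious
  calls from near-zero FPKM; its side effect is that genuine fold changes
  of weakly expressed genes are shrunk below threshold (see Limitations).

## TF profiles and distances

For a selected DE gene set, every transcription factor in a documented
regulation table (YEASTRACT-export style; only `documented-direct` and
`documented-indirect` evidence is kept by default, which also serves as the
guard against promiscuous "general" TF annotations of `potential` evidence)
is scored by the number of DE genes among its targets. The **TF profile**
keeps the top K = 20 TFs with their fraction of the *total* DE gene count
(genes no TF regulates stay in the denominator). Ties at the K-th rank
break lexicographically, so reports are deterministic.

**Conserved TFs** across condition pairs are the intersection of the
profiles' top-K TF name sets — order-independent and idempotent.

To compare a sample profile with a **reference profile** (the same
construction applied to the top 250 genes of an externally ranked DE
list), both fraction vectors are placed on the sorted union of the two
profiles' TF names (zero-filled where absent), rescaled to unit L2 norm,
and compared by Euclidean distance

d = sqrt( Σᵢ (TFᵢ,ₛ − TFᵢ,ᵣ)² ).

L2 normalization is chosen so that d is scale-free and bounded: for
nonnegative unit vectors 0 ≤ d ≤ √2, with √2 exactly when the profiles
share no TF. L1 normalization is available (`norm="l1"`); the union axis
is the default because it uses exactly the reported profile content, with
no external TF universe required.

## GO summarization

Selected genes are grouped by a flat gene → GO-slim mapping: a gene with m
terms appears under m rows but counts once in the per-direction totals;
genes with no annotation land in an "Un-identified" bucket. No ontology
traversal or enrichment statistics — the stage reproduces membership
lists, deterministically and offline.

## Physiology arithmetic

The packaged table `physiology_cty_inv.tsv` stores measured growth rate
(1/h), xylose uptake (mmol/gDCW/h) and product yields (g/g) with their ±
uncertainties for six strains (CTY and INVSc1 hosts × WT/CTYp/INVp xylose
pathways). Percent changes are `100·(new − ref)/ref` rounded half away
from zero to whole percents (the exact value is returned alongside);
uncertainties are carried but not propagated. Two published percent
changes for the uptake rate (a "94%" increase and a "25%" decrease) are
not exactly recomputable from the table's rounded point values (they give
96% and −20%); they were presumably computed from unrounded data, and this
package reports only what it computes from the stored values.

## Synthetic data

The generator stands in for the unavailable raw sequencing data and
defines the conditions under which recovery is tested:

| parameter | default | rationale |
|---|---|---|
| genes | 6000 | order of the yeast transcriptome |
| replicates | 3 per condition | study design |
| log2 baseline | N(5, 2²) | typical FPKM spread over ~4 orders of magnitude |
| replicate noise sd (log2) | 0.12 | calibrated: expected inter-replicate r = 4/(4+0.12²) ≈ 0.996 |
| planted DE genes | 100 | ample for recovery statistics at desk scale |
| planted \|log2FC\| | 2 | free parameter; sign random per gene |
| TFs / target-set size | 50 / 10–50 | sparse bipartite network, realistic YEASTRACT out-degrees |
| conserved TFs / enrichment | 3 / 0.5 | planted regulators receive half of each pair's DE genes |
| ranking noise sd | 0.25 | keeps ≳90 of 100 planted genes in the top 250 of 6000 |

Expression is lognormal-multiplicative (normal on log2) because the
pipeline consumes FPKM, not counts: there is no count-level sampling, no
gene-length or GC bias, no library-size variation, and replicate noise is
i.i.d. across genes. Consequently, passing recovery tests demonstrates
that the *logic* of consensus selection, profile construction and
intersection recovers planted structure under the stated noise level — not
that the pipeline is robust to the full error structure of real RNA-seq
(overdispersion, correlated batch effects, isoform ambiguity).

One integer seed drives each generator through `numpy.random.default_rng`;
multi-artifact runs derive per-artifact sub-seeds deterministically, so
identical configurations are bit-reproducible.

## Numerical choices and degenerate inputs

* Empty DE gene sets are rejected (`InputError`) before profile
  construction — fractions would be undefined; empty profiles are rejected
  before normalization, so unit-norm vectors always exist (asserted to
  1e-9).
* Consensus output is sorted by (support desc, feature id asc); profile
  entries by (count desc, name asc).
* `cutoff_n` must lie in [1, number of pairs]; mismatched feature
  universes across pairwise tables are a hard error rather than an
  implicit intersection.
* The pipeline is a pure function of (inputs, config): reruns produce
  byte-identical reports, and the run manifest records all parameters.

## Problem sizes used in the test suite

Unit and property tests run on matrices of ≤ 800 genes; the acceptance
checks run the full default simulation (6000 genes × 6 samples, four
condition pairs) plus 200 randomized brute-force comparisons, 50
monotonicity instances and 1000 random profile triples. The whole suite
completes in well under a minute on one CPU.

## Known limitations

* The default caller's degenerate p-values make `alpha` inert unless real
  `.diff` files are supplied.
* Down-shifted genes with very low baseline expression can be missed
  because the ε-shrinkage caps their observable fold change — visible in
  simulation as recall slightly below 100%.
* Conserved-TF intersection is a set operation on top-K membership: a TF
  at rank K+1 in one comparison drops out entirely; no enrichment
  statistics or background correction are computed, matching the
  rank-by-raw-count design.
* Transcript → gene collapsing is a user-supplied mapping
  (`apply_feature_mapping`); without it feature ids are treated as genes.
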