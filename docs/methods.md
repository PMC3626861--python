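# Methods

## Scope and data model

The pipeline operates on five in-memory objects: an `InteractionNetwork`
(simple undirected graph over normalized, uppercased gene symbols with
optional per-edge confidence in [0, 1] and source tags), curated
`EvidenceRecord`s (gene × study approach × species × reference),
`Pathway` gene sets, a binary `MembershipMatrix`, and BED-convention
`GenomicInterval`s.  All file formats are plain text (edge-list TSV, GMT,
BED3+, one-symbol-per-line lists), so the whole analysis is inspectable
and diff-able.

## Evidence tallying

A *report* is a distinct (approach, species, reference) triple: two
association studies in the same species count separately, a re-listing of
the same study does not.  This convention is what makes the curated
arithmetic come out (INSL3 = 1 mouse knock-out + 5 human + 1 sheep + 1
dog association reports = 8).  The multi-evidence rule keeps genes with
at least `min_reports` (default 2) reports.  Seven approaches are
recognized: chromosomal aberration, CNV, clinical syndrome,
knock-out/transgenic, association, expression, protein-level.

## Network fusion

Fusion is a union of edge lists: an edge present in k sources carries k
source tags and the **maximum** of its scores (no published aggregation
rule exists; maximum preserves "any source believes this strongly").
Self-loops are dropped with a logged count.  Scores are metadata only:
prediction runs on unweighted topology, and the STRING-style
high-confidence filter (default cutoff 0.7, the conventional
high-confidence bin) is applied only for subnetwork visualization-type
queries.  The original study's fused human PPIN (and hence its 5018-gene
background) is not reconstructable from published material; synthetic
networks and transcribed tables stand in for it.

## Over-representation analysis

Plain upper-tail hypergeometric test against an explicit background
(cohort plus first neighbors), not a whole-genome background.  `k = 0`
short-circuits to 1.  The EASE-style conservative variant (overlap minus
one) is available behind `ease=True` but off by default, since the plain
hypergeometric is the stated test.  The Bonferroni family counts only
pathways with at least one background member — an untestable pathway
carries no hypothesis.  Genes outside the background are dropped from
query and pathways with a warning.  Results sort by adjusted p, ties by
pathway id, for reproducible output.

The tail probability is delegated to `scipy.stats.hypergeom.sf`, which an
exhaustive enumeration oracle confirms to 1e-12 on every instance with
N ≤ 25 (and spot checks at ~3e-16 accuracy overall).

## Guilt-by-association prediction

Only non-seed first neighbors of the cohort are tested (genes with no
seed edge carry no evidence), with universe N = |V| − 1 (all possible
partners of the tested gene), K = |seed ∩ V|, n = degree.  The Bonferroni
family is the number of tested neighbors, matching the restriction of the
question to first neighbors.  N, K and n are emitted per gene so any
alternative universe convention can be audited or recomputed downstream.
Under a seed-free null this controls the family-wise false-positive rate
at α (measured ≈ 0.8–1% at α = 1% over 500 replicates); under the
strong-signal generator defaults every planted gene is recovered with
p_adj many orders of magnitude below α.

## Membership matrix and bi-clustering

Rows are cohort genes belonging to at least one significant pathway
(all-zero rows are excluded at build time: they are undefined under
Jaccard distance), columns the significant pathways, entries 0/1.  The
published filter retains genes in ≥ 2 pathways.

Clustering is agglomerative with Jaccard distance (default; Hamming
optional) and average linkage (complete/single optional).  Two numerical
choices make it fully deterministic:

- cluster-pair distances are computed with exact rational arithmetic
  (`fractions.Fraction`) — Jaccard/Hamming distances on binary vectors
  are rationals and average linkage preserves rationality — so equality
  of distances is decided exactly, never within a float tolerance;
- ties in the minimal distance are broken by the lexicographically
  smallest (min-leaf-label, min-leaf-label) pair.

Merge heights are non-decreasing (average linkage is monotone), `cut(k)`
undoes the k−1 highest merges, and trees serialize to Newick with branch
lengths equal to height differences.  The O(L³·pairs) from-scratch
recomputation is deliberate: the matrices are small (≤ ~100 leaves) and
the exactness is worth more than speed.  On the study matrix the 2-cut of
the pathway axis reproduces the published two-group structure
(muscle/cardiac contraction + both cardiomyopathies vs the eight
signaling pathways); this split is documented as sensitive to the
distance/linkage choice, which the original figure does not name.

## Positional candidates

0-based half-open intervals throughout; adjacency is not overlap; any
1-bp intersection counts; chromosome labels are compared after stripping
a `chr` prefix; strand is ignored.  Overlap is a direct all-pairs scan —
inputs are tens of intervals, so no sweep-line machinery is warranted.
The published findings give cytogenetic bands, not base pairs, so the
packaged BED fixtures use representative synthetic coordinates (flagged
in their headers); only the set-identity of overlap calls is meaningful.

## Prioritization

No weighting formula is published, so the ranking is the most
conservative reading of "meets all of them": sort by criteria met
(report count ≥ 2, pathway participation ≥ 1, positional), then by
report count, pathway count and positional flag, then alphabetically;
every criterion value is emitted so users can re-rank.  Pathway
participation (criterion 2) is counted on the unfiltered significant-
pathway matrix, before the ≥ 2 filter, matching the published per-gene
pathway counts.  The "seven or more pathways" gene set is computed on the
literature-cohort pathway table, whose arithmetic uniquely reproduces the
published six genes (GRB2, HRAS, MAP2K1, MAP2K2, RAF1, SOS1).

## Synthetic data

`SimulationConfig` defaults are the strong-signal study conditions used
throughout the tests: 2000 nodes, Erdős–Rényi p = 0.005 (mean degree
~10, comparable to the candidate neighborhood densities the analysis
assumes), a 50-gene cohort, 20 planted candidates with ≥ 12 distinct
cohort neighbors each, and 20 pathways (5 enriched at 50% cohort/planted
membership, sizes 10–30).  ER is the default background because its
calibration is analytically transparent; a configuration model with a
truncated power-law degree sequence (exponent 2.5, configurable) is
available to emulate PPIN heavy tails.

Planting rewires instead of inflating: a planted gene's spare non-cohort
edges are swapped into the cohort, preserving its total degree where
feasible, so the detectable signal is connectivity *concentration* — the
quantity the hypergeometric neighborhood test measures — not raw degree.
Fresh edges are added only when the gene has no spare edges left.
Everything is a deterministic function of `rng_seed`.

What the generator does **not** emulate: overlapping pathway hierarchies,
degree-correlated (hub-biased) annotation, literature ascertainment bias,
and the modular community structure of real interactomes.  Passing tests
therefore demonstrate correctness and calibration of the statistics under
the stated null/signal models, not biological validity on real PPINs.

## Problem sizes and replicate counts

The test suite uses 500 null replicates (300-node networks) for the
family-wise error check, 100 replicates of the strong-signal
configuration for recovery, 100 replicates per grid point for the
power-monotonicity check (600-node networks), and 2000 permutation
replicates for enrichment calibration; the full suite runs in about half
a minute on one CPU.  The acceptance script uses 100 recovery and 500
null replicates.  These sizes were chosen so Monte-Carlo standard errors
are small relative to the asserted bounds (all stochastic assertions use
a 3×SE margin).

## Known limitations

- Published enrichment p-values depend on a 2012-era annotation corpus
  and an unpublished fused PPIN; they are transcribed as metadata, never
  recomputed, and the packaged background counts (179/5018) are
  documented as non-reproducible.
- The full 179- and 43-gene rosters are unpublished; packaged rosters pad
  the printed symbols with labelled `SYNLIT###`/`SYNNET##` placeholders to
  the stated sizes, and genes printed only in the joint pathway table are
  assigned to the literature cohort.  Whole-cohort counts are exact by
  construction; per-placeholder identities are obviously not real genes.
- The published text is internally inconsistent in two places (a "13
  genes" sentence listing 14 symbols, one of them on a chromosome outside
  the sentence's own list; a "2/5" pathway count for SOS1 vs 8 in its own
  table).  The package reports computed values and does not arbitrate.
- No optimal leaf ordering, heatmap rendering, GO ancestry propagation,
  FDR alternatives to Bonferroni, ortholog mapping, or live database
  retrieval.
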