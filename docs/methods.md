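# Methods

## The comparative design

The pipeline contrasts two clades of bacterial genomes — a
terrestrial-like clade A and an aquatic-like clade B — along four axes:
shared versus clade-exclusive gene content (orthology), allocation of
genes to functional categories (profiles, clustering, ordination),
carbohydrate-active versus proteolytic enzyme repertoires (CAZy /
peptidase accounting), and category enrichment of gene sets
(Fisher's exact test).  Every stage operates on plain per-genome protein
FASTA plus TSV tables, so upstream annotation tools are modeled as
inputs rather than executed.

## Orthology

**Ortholog definition.**  Two proteins from different genomes are
orthologs when each is the other's *unique* top-scoring hit (ties on raw
score disqualify, since a tied best hit is not unique), their alignment
reaches at least 60% similarity, and their lengths differ by less than
30%.  `length_difference_fraction = |len(a) − len(b)| / max(len(a),
len(b))`; the maximum is the symmetric, conservative denominator choice.
Thresholds are applied as ≥ 60 and strictly < 0.30.

**Alignment.**  Smith-Waterman local alignment with BLOSUM62 and affine
gaps (open 11, extend 1 — the BLAST protein defaults), delegated to
`biotite.sequence.align.align_optimal`.  The ambiguity residue X scores
0 against everything, making reads with masked residues neutral rather
than penalized.  Percent similarity is BLAST-style *positives*
(positive-scoring aligned pairs) over the full alignment length
including gap columns; an identity-based mode is selectable
(`similarity_mode="identity"`) because "percent similarity" is used both
ways in the literature.

**Coverage floor.**  A *qualifying* hit must additionally cover at least
50% of the shorter protein (`min_coverage`, settable to 0).  This is a
deliberate design choice: the optimal local alignment between two
*unrelated* ~120-residue proteins is typically an 8–12 column island
scoring ~25 with ≥ 60% positives, so a similarity threshold alone would
certify noise-level hits as homologs and annihilate clade exclusivity.
BLAST-based pipelines discard such hits via the e-value cutoff; a
coverage floor is the deterministic analogue.

**Speed.**  Candidate pairs are prefiltered by shared 4-mers (at least
2); at the divergences of interest family members share tens of intact
4-mers while unrelated pairs share essentially none, so the prefilter
only skips alignments that could not qualify.  `prefilter_k=None`
disables it.

**Families and partitions.**  Families are connected components of the
union RBH graph over all genome pairs (singletons included).  The core
genome requires presence in every genome — exactly one member per genome
in strict mode (default), at least one in relaxed mode.  Niche
specificity for clade A requires presence in every clade-A reference
genome and the absence of *any* qualifying hit (not necessarily
reciprocal-best: any homolog falsifies exclusivity) in every clade-B
reference genome.  Partition summaries count a family as hypothetical
when at least half its members are flagged, and report integer-rounded
percentages alongside raw fractions.

## Functional profiles and clade tests

Per-genome counts over level-1 categories or level-2 subsystems are
divided by the genome's **total** gene count (user-suppliable, since the
annotated subset may be smaller than the genome).  A protein carrying
several categories counts once per category, matching subsystem-style
tallies.  Clades are compared per category with the pooled-variance
Student t-test (two-sided, alpha 0.05); Welch is available by flag.  No
multiple-testing correction gates the default significance flag — the
per-category *P* < 0.05 rule is the study convention — but a
Benjamini-Hochberg column is always emitted so users can filter on it.
Degenerate categories (zero variance in both clades, equal means) yield
t = 0, p = 1 rather than an error.

## Clustering and ordination

Bray-Curtis dissimilarity on non-negative profiles; an all-zero pair is
an error (the measure is undefined there).  UPGMA uses
`scipy.cluster.hierarchy.linkage(method="average")`; scipy's
deterministic merge order is the tie rule.  Bootstrap support resamples
profile *columns* with replacement (the standard convention for profile
clustering), rebuilds the tree, and scores each original internal
bipartition by the percentage of replicates containing it; a replicate
that zeroes out a genome's whole profile is redrawn.  Bipartitions are
canonicalized as the side not containing the lexicographically smallest
label, so support lookup is rooting-independent.  Trees are exported as
Newick with supports as internal node labels.

nMDS minimizes Kruskal stress-1, computed in-package as
`sqrt(Σ(d − d̂)² / Σd²)` with disparities `d̂` from isotonic regression
(ties averaged) of configuration distances on observed dissimilarities.
Optimization is SMACOF (`sklearn.manifold.smacof`, nonmetric) from a
classical-scaling (Torgerson) first start plus seeded random restarts;
the raw classical configuration remains a candidate, so the returned
stress can never exceed the initialization's.  Classical-scaling axes
are sign-canonicalized (largest-magnitude coordinate positive), which
makes single-start results equivariant under label permutation.
Non-convergence returns the best-so-far configuration with a warning.

## Enzyme accounting

Consensus annotation keeps a (protein, family) call iff both declared
predictors make it — at exact family level by default, at class level
(GH/CE/PL/CBM/GT, everything else PEP) by option, since "both methods
agree" is ambiguous about granularity.  Counting is at assignment
(domain) level: a call made twice by both sources counts twice.
Clade-unique families require a positive count in at least
`presence_fraction` (default 0.5) of the focal clade's genomes and zero
in every genome of the other clade; both knobs are exposed because
published "clade-unique" tables include families absent from some focal
strains.  Shannon diversity uses the natural logarithm and is computable
over families or aggregated classes.  The peptidase/GH ratio divides
peptidase counts by GH counts per genome; a GH-free genome is flagged
and excluded from the clade mean rather than producing an infinity.

The packaged 15-strain *Flavobacterium* count table (published data,
keyed in as a plain TSV) serves as a real-data fixture: at the default
thresholds the rhamnogalacturonan families GH78 and GH106 come out
terrestrial-unique, and GH130 does not (one aquatic strain carries it).

## Enrichment

One-tailed (over-representation) Fisher's exact test: the p-value is the
hypergeometric upper tail P(X ≥ k) for k category hits among n inspected
proteins given K hits among N reference proteins.  Representation ratio
(k/n)/(K/N) reports direction; under-representation is shown by ratios
below 1, not by a second test.  The inspected set must live inside the
reference universe unless `disjoint_universe=True`, which tests against
the union.  BH-adjusted p-values are emitted; the unadjusted alpha
filter remains the default selection rule.

## Synthetic data: what it emulates, what it does not

The generator plants, per family, an ancestral random sequence (lengths
normal, mean 120 sd 25, floor 40) copied into each member genome with
independent per-site substitutions at the configured divergence
(substitutions uniform over the 19 alternatives; lengths preserved by
default, with an optional geometric-indel mode to exercise the length
filter).  Defaults: 4 + 3 genomes, 50 core, 20 A-specific, 10
B-specific, 5 private families per genome, divergence 0.15.  At 0.15
within-family identity is ≈ (1−d)² ≈ 72% — comfortably above the 60%
similarity threshold — while at 0.45 it falls to ≈ 31%, far below it,
so recovery should be exact in the first regime and zero-core in the
second.

Functional labels are drawn per protein from clade-specific category
distributions (terrestrial-like clade: 28% carbohydrates vs 8% protein
metabolism; aquatic-like clade: 10% vs 24%; shared housekeeping mass
elsewhere, 20% hypothetical in both).  Enzyme content is planted per
genome: GH totals Poisson (mean 30 terrestrial-like, 8 aquatic-like,
drawn from clade-specific family pools in which GH78/GH106 are
terrestrial-only), peptidase totals `round(ratio_g × GH_g)` with
`ratio_g` = planted ratio (1.7 / 9.7) plus N(0, 0.3) noise — so the
planted clade ratio is recoverable to a few tenths from five genomes,
which pure independent Poisson draws would not guarantee.  Both
predictors emit the planted family; a configurable disagreement rate
makes the second source emit a family the first source never assigns
that protein (so full disagreement provably empties the consensus).
Generation is bit-identical under a fixed seed, and the generator
verifies at build time that mean between-clade Bray-Curtis distance
exceeds mean within-clade distance whenever the clade profiles differ.

An auxiliary generator produces idealized Gaussian two-clade profile
matrices (defaults: 5 + 5 genomes, 30 categories of which 15 shifted by
3 pooled SDs) for clustering/bootstrap/t-test checks, and another
produces exact Euclidean distance matrices from planted 2-D
configurations for nMDS recovery.

What the synthetic data does *not* emulate: domain architecture and
partial homology (families are all-or-nothing), horizontal transfer,
paralog expansion beyond private singletons, codon-level evolution,
annotation noise in category labels, and genome-size variation beyond
family counts.  Passing recovery tests therefore demonstrates the
correctness of the machinery under the planted model, not the
biological accuracy of any particular threshold on real genomes.

## Problem sizes and numerical choices

Test and acceptance runs use the default simulator scale (seven genomes,
~500 proteins) — large enough that every planted structure is
statistically unambiguous, small enough to iterate quickly.  Exhaustive
oracles are exact: the Fisher check enumerates all consistent margins to
N ≤ 40 with integer arithmetic; the alignment oracle is a naive Gotoh
dynamic program over hundreds of short random pairs.  Matrix round-trips
hold to 10 significant digits (the TSV writer's precision).  Reported
stress values are always Kruskal stress-1 of the returned configuration,
never the optimizer's internal objective.

## Known limitations

The RBH stage is quadratic per genome pair and meant for tens, not
thousands, of genomes.  The coverage floor and k-mer prefilter are
pragmatic substitutes for e-value statistics; analyses that need
BLAST-exact hit sets should export the thresholds and rerun with a
dedicated search tool.  The UPGMA tie rule is scipy's, not a published
convention.  Enrichment treats categories independently (no hierarchy
propagation).
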