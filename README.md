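# nichecomp

Comparative pangenomics of habitat adaptation in bacteria, built around
the question that motivates flavobacterial genomics: what separates the
genomes of terrestrial (soil/rhizosphere) strains from those of aquatic
strains?  Terrestrial *Flavobacterium* genomes are larger, carry a rich
repertoire of plant-glycan-degrading enzymes (including the
rhamnogalacturonan-specific glycoside hydrolase families GH78 and
GH106), while aquatic strains lean on peptide and protein utilization —
a contrast captured by a single statistic, the peptidase/GH ratio.

`nichecomp` implements that comparative analysis as a reusable, tested
pipeline:

- **Orthology** — orthologs are *unique pairwise reciprocal best hits*
  between proteomes (Smith-Waterman, BLOSUM62, gap 11/1) with at least
  60% amino-acid similarity and less than 30% protein-length difference.
  Multi-genome ortholog families are connected components of the RBH
  graph; the **core genome** is the families present in every genome,
  and a clade's **niche-specific genome** is the families present in all
  of that clade's reference genomes with no qualifying homolog in the
  other clade's references.
- **Functional profiles** — per-genome gene counts over a two-level
  category hierarchy, normalized to total gene count; clades compared
  per category by pooled-variance Student t-test (*P* < 0.05).
- **Clustering & ordination** — Bray-Curtis dissimilarity
  BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), UPGMA dendrograms with 1000
  column-bootstrap support values, and nonmetric MDS minimizing Kruskal
  stress-1.
- **Enzyme accounting** — CAZy/peptidase family calls retained only when
  two predictors agree; genomes × families count matrices, clade-unique
  families, Shannon diversity H = −Σ pᵢ ln pᵢ, and the peptidase/GH
  lifestyle ratio with clade means ± SD.
- **Enrichment** — one-tailed Fisher's exact test (hypergeometric upper
  tail) with representation ratios (k/n)/(K/N).
- **Synthetic pangenomes** — a generator that plants core,
  clade-specific and private gene families at controlled sequence
  divergence, clade-biased functional labels and clade-typical
  peptidase/GH ratios, returning a machine-readable truth set so every
  stage's recovery can be checked exactly.

## Worked example

The `analysis/` scripts run the whole study on the default synthetic
design (4 terrestrial-like + 3 aquatic-like genomes, 50 core / 20
A-specific / 10 B-specific planted families, divergence 0.15):

```bash
python analysis/01_simulate.py
python analysis/02_orthology.py
python analysis/03_functional_profiles.py
python analysis/04_cluster_ordination.py
python analysis/05_cazy_peptidase.py
python analysis/06_enrichment.py
```

which prints, among other things:

```
115 ortholog families across 7 genomes
  core: 50 families, 2 hypothetical (4%)
  niche_specific_A: 20 families, 6 hypothetical (30%)
  niche_specific_B: 10 families, 2 hypothetical (20%)
...
2 categories differ between clades at P<0.05:
  Carbohydrates: t=12.42 p=5.99e-05 (terrestrial-enriched)
  Protein Metabolism: t=-5.24 p=3.36e-03 (aquatic-enriched)
...
  peptidase/GH ratio clade A: 1.88 ± 0.34 (n=4)
  peptidase/GH ratio clade B: 9.68 ± 0.31 (n=3)
published 15-strain table: 13 terrestrial-unique families; GH78/GH106 included: True
```

The orthology stage recovers the planted 50/20/10 partition exactly; the
clade contrast planted into the functional labels surfaces as
carbohydrate enrichment in the terrestrial-like clade and
protein-metabolism enrichment in the aquatic-like clade; the planted
lifestyle ratios (1.7 vs 9.7) are recovered within sampling noise; and
on the published 15-strain *Flavobacterium* CAZy count table the
rhamnogalacturonan marker families GH78/GH106 emerge terrestrial-unique.
Tables land under `results/`.

The same stages are available as a CLI (`nichecomp simulate|orthology|
profiles|cluster|cazy|enrich|run`); `nichecomp run --seed 1 --out DIR`
executes everything with a reproducibility manifest.

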