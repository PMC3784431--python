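#!/usr/bin/env python
"""Functional enrichment of the terrestrial niche-specific genome.

Tests each functional category for over-representation among clade-A
niche-specific proteins relative to the full annotated complement of the
clade-A reference genomes, using the one-tailed Fisher's exact test, and
reports representation ratios (>1 over-, <1 under-represented).
"""

from pathlib import Path

import pandas as pd

from nichecomp.enrichment import enrich
from nichecomp.io_model import read_annotations, read_design

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = read_design(BASE / "data" / "design.tsv")
    annotations = read_annotations(BASE / "data" / "annotations.tsv")
    partition = pd.read_csv(BASE / "partition.tsv", sep="\t")
    families = pd.read_csv(BASE / "families.tsv", sep="\t")

    spec_fids = set(partition.loc[partition["set"] == "niche_specific_A", "family_id"])
    members = families[families["family_id"].isin(spec_fids)]
    ref_genomes = set(design.reference("A"))

    ann = annotations.assign(key=annotations["genome_id"] + ":" + annotations["protein_id"])
    ref_map = ann.loc[ann["genome_id"].isin(ref_genomes), ["key", "level1_category"]]
    spec_keys = {
        f"{g}:{p}" for g, p in members[["genome_id", "protein_id"]].itertuples(index=False)
        if g in ref_genomes
    }
    set_map = ref_map[ref_map["key"].isin(spec_keys)]

    table = enrich(set_map, ref_map)
    table.to_csv(BASE / "enrichment.tsv", sep="\t", index=False)
    print(f"{len(set_map)} niche-specific protein annotations vs "
          f"{len(ref_map)} reference annotations")
    for _, row in table.iterrows():
        marker = "*" if row["significant"] else " "
        print(f" {marker} {row['category']}: ratio={row['representation_ratio']:.2f} "
              f"p={row['p_value']:.3g}")


if __name__ == "__main__":
    main()
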