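#!/usr/bin/env python
"""Reciprocal-best-hit orthology: core and niche-specific genomes.

Reads the simulated proteomes from results/data/, builds RBH ortholog
families (similarity ≥ 60%, length difference < 30%), partitions them
into core / A-specific / B-specific / accessory, and reports the
hypothetical-protein share of each set (hypothetical = annotated to the
'Hypothetical' category).
"""

from pathlib import Path

import pandas as pd

from nichecomp.io_model import read_annotations, read_design, read_proteome
from nichecomp.orthology import build_families, partition_families, summarize_partition

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = read_design(BASE / "data" / "design.tsv")
    proteomes = {
        p.stem: read_proteome(p, clade=design.clades.get(p.stem))
        for p in sorted((BASE / "data").glob("*.faa"))
    }
    annotations = read_annotations(BASE / "data" / "annotations.tsv")

    families = build_families(list(proteomes.values()))
    partition = partition_families(families, proteomes, design)
    flags = {
        (g, p): cat == "Hypothetical"
        for g, p, cat in annotations[
            ["genome_id", "protein_id", "level1_category"]
        ].itertuples(index=False)
    }
    report = summarize_partition(partition, families, flags)

    pd.DataFrame(
        [(f.family_id, g, p) for f in families for (g, p) in sorted(f.members)],
        columns=["family_id", "genome_id", "protein_id"],
    ).to_csv(BASE / "families.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(fid, role)
         for role in ("core", "niche_specific_A", "niche_specific_B", "accessory")
         for fid in sorted(getattr(partition, role))],
        columns=["family_id", "set"],
    ).to_csv(BASE / "partition.tsv", sep="\t", index=False)

    print(f"{len(families)} ortholog families across {len(proteomes)} genomes")
    for name, entry in report.items():
        line = f"  {name}: {entry['size']} families"
        if entry["size"]:
            line += f", {entry['hypothetical']} hypothetical ({entry['percent']}%)"
        print(line)


if __name__ == "__main__":
    main()
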