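#!/usr/bin/env python
"""Normalized functional profiles and clade t-tests.

Counts annotated genes per SEED-style category, normalizes by each
genome's total gene count, and tests every category for a
terrestrial/aquatic difference with a pooled-variance Student t-test
(alpha = 0.05, Benjamini-Hochberg column alongside).
"""

from pathlib import Path

from nichecomp.io_model import read_annotations, read_design, read_proteome, write_matrix
from nichecomp.profiles import build_profiles, compare_clades

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = read_design(BASE / "data" / "design.tsv")
    proteomes = {
        p.stem: read_proteome(p, clade=design.clades.get(p.stem))
        for p in sorted((BASE / "data").glob("*.faa"))
    }
    annotations = read_annotations(BASE / "data" / "annotations.tsv")
    profiles = build_profiles(annotations, proteomes, level=1)
    write_matrix(profiles, BASE / "profiles.tsv")
    comparison = compare_clades(profiles, design)
    comparison.to_csv(BASE / "clade_comparison.tsv", sep="\t", index=False)

    sig = comparison[comparison["significant"]]
    print(f"profiles: {profiles.shape[0]} genomes x {profiles.shape[1]} categories")
    print(f"{len(sig)} categories differ between clades at P<0.05:")
    for _, row in sig.iterrows():
        direction = "terrestrial-enriched" if row["t_statistic"] > 0 else "aquatic-enriched"
        print(f"  {row['category']}: t={row['t_statistic']:.2f} "
              f"p={row['p_value']:.2e} ({direction})")


if __name__ == "__main__":
    main()
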