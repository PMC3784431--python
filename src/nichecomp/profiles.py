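"""Normalized functional profiles and clade-by-clade category comparison.

Per-genome gene counts over a two-level functional hierarchy (SEED-style
category / subsystem) are normalized to the genome's *total* gene count,
so genomes of different sizes are comparable.  Clades are compared one
category at a time with a two-sample Student t-test (pooled variance,
two-sided) at alpha = 0.05; a Benjamini-Hochberg column is emitted
alongside the raw p-values for transparency but does not drive the
default significance flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import CladeDesign, Proteome

_LEVEL_COLUMN = {1: "level1_category", 2: "level2_subsystem"}


def build_profiles(
    annotations: pd.DataFrame,
    proteomes: dict[str, Proteome],
    level: int = 1,
) -> pd.DataFrame:
    """Genomes × categories relative-abundance matrix.

    Each (protein, category) assignment counts once — a protein carrying
    several categories contributes to each of them — and counts are
    divided by the genome's ``total_genes``.  Categories absent from a
    genome are harmonized to 0.  Row order follows sorted genome ids.
    """
    if level not in _LEVEL_COLUMN:
        raise ValueError("level must be 1 or 2")
    col = _LEVEL_COLUMN[level]
    for _, row in annotations.iterrows():
        g = row["genome_id"]
        if g not in proteomes:
            raise ValueError(f"annotation references unknown genome {g!r}")
        if row["protein_id"] not in proteomes[g]:
            raise ValueError(
                f"annotation references unknown protein {row['protein_id']!r} in {g!r}"
            )
    dedup = annotations.drop_duplicates(subset=["genome_id", "protein_id", col])
    counts = (
        dedup.groupby(["genome_id", col]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=sorted(proteomes), fill_value=0)
    counts = counts[sorted(counts.columns)]
    totals = pd.Series({g: float(p.total_genes) for g, p in proteomes.items()})
    profile = counts.div(totals, axis=0)
    profile.index.name = "genome_id"
    return profile


def compare_clades(
    profiles: pd.DataFrame,
    design: CladeDesign,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-category two-sample t-test between the two clades.

    Student (pooled-variance) by default; ``equal_var=False`` switches to
    Welch.  The t statistic is signed as mean(A) − mean(B) with A the
    lexicographically first clade label.  Zero variance in both groups
    with equal means yields t = 0, p = 1.  Rows are sorted by p-value.
    """
    clade_a, clade_b = design.clade_labels[:2]
    ga = [g for g in design.genomes(clade_a) if g in profiles.index]
    gb = [g for g in design.genomes(clade_b) if g in profiles.index]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least two genomes per clade")
    rows = []
    for cat in profiles.columns:
        a = profiles.loc[ga, cat].to_numpy(dtype=float)
        b = profiles.loc[gb, cat].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "category": cat,
                "mean_A": a.mean(),
                "sd_A": a.std(ddof=1),
                "mean_B": b.mean(),
                "sd_B": b.std(ddof=1),
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_value"] < alpha
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
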