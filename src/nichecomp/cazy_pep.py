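"""Consensus enzyme-family accounting and the peptidase/GH lifestyle ratio.

Carbohydrate-active enzyme (CAZy) families are trusted only when two
independent predictors agree; agreed assignments are tallied into a
genomes × families count matrix from which clade-unique families,
Shannon diversity and the peptidase-to-glycoside-hydrolase ratio are
derived.  The ratio is the lifestyle statistic: protein/peptide-centric
(aquatic-type) genomes run high, glycan-centric (terrestrial-type)
genomes run low.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import CladeDesign

_CAZY_RE = re.compile(r"^(GH|CE|PL|CBM|GT)\d+$")

#: CAZy classes; anything else (MEROPS-style tokens) is a peptidase
CAZY_CLASSES = ("GH", "CE", "PL", "CBM", "GT")


def family_class(family: str) -> str:
    """Map a family token to its class: GH/CE/PL/CBM/GT, or PEP."""
    m = _CAZY_RE.match(family)
    return m.group(1) if m else "PEP"


def consensus_annotation(predictions: pd.DataFrame, mode: str = "family") -> pd.DataFrame:
    """Assignments on which both predictors agree.

    ``mode="family"``: a (protein, family) assignment survives iff both
    sources assign that exact family; a protein may retain several agreed
    families.  ``mode="class"``: agreement is required only at class
    level and the surviving assignment is the class token itself.
    Counting is at assignment (domain) level: an assignment predicted
    twice by both sources survives twice, i.e. each (protein, family)
    keeps multiplicity min(count by source 1, count by source 2).
    Requires exactly two prediction sources.
    """
    if mode not in ("family", "class"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    sources = sorted(predictions["source"].unique())
    if len(sources) != 2:
        raise ValueError(f"consensus requires exactly 2 sources, found {sources}")
    df = predictions.copy()
    if mode == "class":
        df["family"] = df["family"].map(family_class)
    key = ["genome_id", "protein_id", "family"]
    counts = (
        df.groupby(key + ["source"]).size().unstack("source", fill_value=0)
    )
    mult = counts[sources[0]].clip(upper=counts[sources[1]])
    agreed = [
        tup for tup, m in mult.items() for _ in range(int(m))
    ]
    return pd.DataFrame(sorted(agreed), columns=key)


@dataclass
class FamilyCountMatrix:
    """Genomes × enzyme-family integer counts with a family → class map."""

    counts: pd.DataFrame
    classes: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("family counts must be non-negative")
        unmapped = set(self.counts.columns) - set(self.classes)
        if unmapped:
            raise ValueError(f"families without a class: {sorted(unmapped)[:5]}")

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    def class_counts(self) -> pd.DataFrame:
        """Counts aggregated from families to classes."""
        groups = pd.Series(self.classes).reindex(self.counts.columns)
        return self.counts.T.groupby(groups).sum().T

    def of_class(self, cls: str) -> pd.DataFrame:
        fams = [f for f in self.counts.columns if self.classes[f] == cls]
        return self.counts[fams]


def family_matrix(
    consensus: pd.DataFrame, genomes: list[str] | None = None
) -> FamilyCountMatrix:
    """Tally agreed (protein, family) assignments per genome.

    Counting is at assignment (domain) level: each agreed row contributes
    one count.  ``genomes`` fixes the row set (genomes with no agreed
    assignment get an all-zero row); by default rows are the genomes seen
    in the consensus.
    """
    if consensus.empty:
        idx = sorted(genomes) if genomes else []
        return FamilyCountMatrix(pd.DataFrame(index=idx, dtype=int), {})
    counts = (
        consensus.groupby(["genome_id", "family"]).size().unstack(fill_value=0)
    )
    if genomes is not None:
        counts = counts.reindex(index=sorted(genomes), fill_value=0)
    counts = counts[sorted(counts.columns)].astype(int)
    counts.index.name = "genome_id"
    return FamilyCountMatrix(counts, {f: family_class(f) for f in counts.columns})


def clade_unique_families(
    matrix: FamilyCountMatrix,
    design: CladeDesign,
    clade: str,
    presence_fraction: float = 0.5,
) -> set[str]:
    """Families found in one clade only.

    A family is unique to ``clade`` iff its count is positive in at least
    ``presence_fraction`` of that clade's genomes and zero in *every*
    genome of the other clade.  Raising ``presence_fraction`` can only
    shrink the result.
    """
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must be in (0, 1]")
    own = [g for g in design.genomes(clade) if g in matrix.counts.index]
    other = [
        g
        for g in design.genomes(design.other(clade))
        if g in matrix.counts.index
    ]
    if not own or not other:
        raise ValueError("both clades must have genomes in the matrix")
    out = set()
    for fam in matrix.counts.columns:
        present = (matrix.counts.loc[own, fam] > 0).sum()
        if present / len(own) < presence_fraction:
            continue
        if (matrix.counts.loc[other, fam] > 0).any():
            continue
        out.add(fam)
    return out


def shannon(counts) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ (natural log) of a count vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an all-zero vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_by_genome(matrix: FamilyCountMatrix, level: str = "family") -> pd.Series:
    """Per-genome Shannon diversity over families or aggregated classes."""
    if level == "family":
        table = matrix.counts
    elif level == "class":
        table = matrix.class_counts()
    else:
        raise ValueError("level must be 'family' or 'class'")
    return pd.Series(
        {g: shannon(table.loc[g].to_numpy()) for g in table.index if table.loc[g].sum() > 0},
        name=f"shannon_{level}",
    )


@dataclass
class LifestyleRatioReport:
    """Per-genome peptidase/GH ratios and per-clade mean ± sample SD."""

    per_genome: pd.DataFrame  # genome_id, clade, peptidase_count, gh_count, ratio, flagged
    per_clade: pd.DataFrame  # clade, mean, sd, n


def load_flavobacterium_counts() -> tuple[FamilyCountMatrix, CladeDesign]:
    """Packaged real-data fixture: published CAZy family counts for 15
    Flavobacterium strains with their terrestrial/aquatic clade labels."""
    from importlib.resources import files

    path = files("nichecomp.data").joinpath("flavobacterium_cazy_counts.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    design = CladeDesign(clades=dict(zip(df["genome_id"], df["clade"])))
    counts = df.drop(columns=["clade"]).set_index("genome_id")
    matrix = FamilyCountMatrix(counts, {f: family_class(f) for f in counts.columns})
    return matrix, design


def lifestyle_ratio(matrix: FamilyCountMatrix, design: CladeDesign) -> LifestyleRatioReport:
    """Peptidase count over glycoside-hydrolase count, per genome and clade.

    Genomes with no GH genes have an undefined ratio: they are flagged
    and excluded from the clade mean rather than silently dropped.
    """
    classes = set(matrix.classes.values())
    if "PEP" not in classes or "GH" not in classes:
        raise ValueError("matrix must contain both peptidase (PEP) and GH families")
    pep = matrix.of_class("PEP").sum(axis=1)
    gh = matrix.of_class("GH").sum(axis=1)
    rows = []
    for g in matrix.genomes:
        flagged = gh[g] == 0
        rows.append(
            {
                "genome_id": g,
                "clade": design.clades.get(g),
                "peptidase_count": int(pep[g]),
                "gh_count": int(gh[g]),
                "ratio": math.nan if flagged else pep[g] / gh[g],
                "flagged": bool(flagged),
            }
        )
    per_genome = pd.DataFrame(rows)
    clade_rows = []
    for clade in design.clade_labels:
        r = per_genome.loc[
            (per_genome["clade"] == clade) & ~per_genome["flagged"], "ratio"
        ]
        clade_rows.append(
            {
                "clade": clade,
                "mean": r.mean() if len(r) else math.nan,
                "sd": r.std(ddof=1) if len(r) > 1 else math.nan,
                "n": len(r),
            }
        )
    return LifestyleRatioReport(per_genome=per_genome, per_clade=pd.DataFrame(clade_rows))
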