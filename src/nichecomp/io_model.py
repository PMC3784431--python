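"""Shared data model and readers/writers for every pipeline stage.

All tabular artifacts use a single dialect: tab-separated UTF-8 with a
header row; lines starting with ``#`` are comments.  Protein sequences are
multi-record FASTA.  Matrices round-trip bit-identically through
:func:`write_matrix`/:func:`read_matrix` at the declared decimal precision.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("nichecomp")

#: the 20 standard amino acids plus X (any/ambiguous)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
#: residues outside the model alphabet are mapped to X on read
_NONSTANDARD = re.compile(r"[BJZOU\*]")

ANNOTATION_COLUMNS = [
    "genome_id",
    "protein_id",
    "level1_category",
    "level2_subsystem",
    "source",
]
PREDICTION_COLUMNS = ["genome_id", "protein_id", "family", "source"]
DESIGN_COLUMNS = ["genome_id", "clade", "is_reference"]


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging to stderr."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


@dataclass
class Proteome:
    """One genome's predicted protein complement.

    Parameters
    ----------
    genome_id : str
        Unique genome label.
    proteins : list of (protein_id, sequence)
        Ordered protein records; order is preserved from the source file.
    total_genes : int
        Total number of gene coding sequences in the genome, used as the
        denominator when profiles are normalized.  May exceed the number
        of proteins held here (e.g. when only an annotated subset is
        loaded); defaults to the protein count.
    clade : str, optional
        Habitat/clade label, if known.
    """

    genome_id: str
    proteins: list[tuple[str, str]]
    total_genes: int | None = None
    clade: str | None = None
    _index: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.total_genes is None:
            self.total_genes = len(self.proteins)
        ids = [p for p, _ in self.proteins]
        dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dupes:
            raise ValueError(
                f"duplicate protein id(s) in genome {self.genome_id!r}: {sorted(dupes)}"
            )
        for pid, seq in self.proteins:
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r} in {self.genome_id!r}")
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"invalid residue(s) {sorted(bad)} in protein {pid!r}"
                )
        if self.total_genes < len(self.proteins):
            raise ValueError(
                f"total_genes ({self.total_genes}) < number of proteins "
                f"({len(self.proteins)}) for genome {self.genome_id!r}"
            )
        self._index = {pid: seq for pid, seq in self.proteins}

    @property
    def protein_ids(self) -> list[str]:
        return [pid for pid, _ in self.proteins]

    def sequence(self, protein_id: str) -> str:
        return self._index[protein_id]

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index


@dataclass
class CladeDesign:
    """Assignment of genomes to two clades plus the reference subsets used
    for niche-specific calls.

    ``clades`` maps every analyzed genome to exactly one clade label; the
    per-clade ``references`` are the (typically closed/completed) genomes
    against which presence and cross-clade absence are evaluated.
    """

    clades: dict[str, str]
    references: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = sorted(set(self.clades.values()))
        if len(labels) < 2:
            raise ValueError("a clade design needs at least two clades")
        if not self.references:
            self.references = {
                lab: {g for g, c in self.clades.items() if c == lab} for lab in labels
            }
        for lab, refs in self.references.items():
            if not refs:
                raise ValueError(f"empty reference subset for clade {lab!r}")
            wrong = {g for g in refs if self.clades.get(g) != lab}
            if wrong:
                raise ValueError(
                    f"reference genomes {sorted(wrong)} not assigned to clade {lab!r}"
                )

    @property
    def clade_labels(self) -> list[str]:
        return sorted(set(self.clades.values()))

    def genomes(self, clade: str) -> list[str]:
        self._check(clade)
        return sorted(g for g, c in self.clades.items() if c == clade)

    def reference(self, clade: str) -> list[str]:
        self._check(clade)
        return sorted(self.references[clade])

    def other(self, clade: str) -> str:
        """The opposite clade label (designs used here are two-clade)."""
        self._check(clade)
        others = [c for c in self.clade_labels if c != clade]
        if len(others) != 1:
            raise ValueError("'other' clade is ambiguous for >2 clades")
        return others[0]

    def _check(self, clade: str) -> None:
        if clade not in set(self.clades.values()):
            raise KeyError(f"unknown clade label {clade!r}")


def read_proteome(
    path: str | Path,
    genome_id: str | None = None,
    total_genes: int | None = None,
    clade: str | None = None,
) -> Proteome:
    """Read one genome's proteins from a multi-record protein FASTA.

    Record order is preserved.  Sequences are upper-cased and non-standard
    residues (B, J, Z, O, U, ``*``) are mapped to X.  Duplicate record ids
    and empty files are hard errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    proteins = []
    for rec in records:
        seq = _NONSTANDARD.sub("X", str(rec.seq).upper().replace("-", ""))
        proteins.append((rec.id, seq))
    return Proteome(
        genome_id=genome_id or path.stem,
        proteins=proteins,
        total_genes=total_genes,
        clade=clade,
    )


def write_proteome(proteome: Proteome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome.proteins:
            fh.write(f">{pid}\n{seq}\n")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a functional annotation table (SEED-style category/subsystem).

    Expects the five columns of :data:`ANNOTATION_COLUMNS`; extra columns
    are ignored.  Returns a DataFrame restricted to the known columns.
    """
    df = _read_tsv(path)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    df = df[ANNOTATION_COLUMNS].copy()
    for col in ("level1_category", "level2_subsystem"):
        if (df[col].fillna("") == "").any():
            raise ValueError(f"{path}: empty values in column {col!r}")
    return df


_FAMILY_RE = re.compile(r"^(GH|CE|PL|CBM|GT)\d+$|^[ASCGIMNPTU]\d+[A-Z]?$")


def read_predictions(path: str | Path, sources: tuple[str, str] | None = None) -> pd.DataFrame:
    """Read an enzyme-family prediction table (CAZy / peptidase).

    Family tokens must look like CAZy families (GH78, CBM6, ...) or
    MEROPS-style peptidase families (S8, M16A, ...).  If ``sources`` is
    given, every row's source must be one of the two declared predictors.
    """
    df = _read_tsv(path)
    _require_columns(df, PREDICTION_COLUMNS, path)
    keep = PREDICTION_COLUMNS + (["score"] if "score" in df.columns else [])
    df = df[keep].copy()
    bad = sorted(set(df["family"]) - {f for f in df["family"] if _FAMILY_RE.match(str(f))})
    if bad:
        raise ValueError(f"{path}: unrecognized family token(s) {bad[:5]}")
    if sources is not None:
        unknown = sorted(set(df["source"]) - set(sources))
        if unknown:
            raise ValueError(f"{path}: undeclared prediction source(s) {unknown}")
    return df


def read_design(path: str | Path) -> CladeDesign:
    """Read a clade-design table: genome_id, clade, is_reference (0/1)."""
    df = _read_tsv(path)
    _require_columns(df, DESIGN_COLUMNS, path)
    if df["genome_id"].duplicated().any():
        dup = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"{path}: genome(s) assigned more than once: {dup}")
    clades = dict(zip(df["genome_id"], df["clade"]))
    refs: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        if str(row["is_reference"]).strip() in {"1", "true", "True"}:
            refs.setdefault(row["clade"], set()).add(row["genome_id"])
    for lab in set(clades.values()):
        refs.setdefault(lab, {g for g, c in clades.items() if c == lab})
    return CladeDesign(clades=clades, references=refs)


def write_design(design: CladeDesign, path: str | Path) -> None:
    rows = []
    for g in sorted(design.clades):
        c = design.clades[g]
        rows.append((g, c, int(g in design.references.get(c, set()))))
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_matrix(
    matrix: pd.DataFrame,
    path: str | Path,
    precision: int = 10,
    allow_nan: bool = False,
) -> None:
    """Write a labeled 2-D table as TSV, round-trippable via :func:`read_matrix`."""
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("row/column labels must be unique")
    values = matrix.to_numpy(dtype=float)
    if not allow_nan and not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries (pass allow_nan=True to permit)")
    matrix.to_csv(path, sep="\t", float_format=f"%.{precision}g", index_label="id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
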