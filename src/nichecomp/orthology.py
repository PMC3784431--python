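"""Reciprocal-best-hit orthology and core / niche-specific genome calls.

The ortholog definition is operational: two proteins from different
genomes are orthologs when each is the other's *unique* top-scoring local
alignment hit, the alignment shows at least ``min_similarity`` percent
similarity, and the two protein lengths differ by less than
``max_length_diff`` (fraction of the longer).  Multi-genome ortholog
families are connected components of the union RBH graph; the core genome
is the set of families present in every genome, and a clade's
niche-specific genome is the set of families present in all of that
clade's reference genomes with no qualifying homolog in any reference
genome of the opposite clade.

Alignment is Smith-Waterman (BLOSUM62, gap open 11 / extend 1, the BLAST
defaults).  Percent similarity is BLAST-style positives over the full
alignment length (gap columns included); an identity-based mode is
selectable.  Because an optimal *local* alignment between unrelated
proteins is typically a short, high-scoring island, a qualifying hit must
additionally cover at least ``min_coverage`` of the shorter protein —
without this floor, clade-exclusivity tests would be falsified by
noise-level alignments a BLAST e-value cutoff would have discarded.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .io_model import CladeDesign, Proteome

#: default ortholog thresholds
MIN_SIMILARITY = 60.0
MAX_LENGTH_DIFF = 0.3
MIN_COVERAGE = 0.5

_GAP_PENALTY = (-11, -1)


def _substitution_matrix() -> balign.SubstitutionMatrix:
    """BLOSUM62 with X scoring 0 against everything (neutral ambiguity)."""
    std = balign.SubstitutionMatrix.std_protein_matrix()
    scores = std.score_matrix().copy()
    alph = std.get_alphabet1()
    x = alph.encode("X")
    scores[x, :] = 0
    scores[:, x] = 0
    return balign.SubstitutionMatrix(alph, alph, scores)


_MATRIX = _substitution_matrix()
_SCORES = _MATRIX.score_matrix()


@dataclass(frozen=True)
class PairwiseHit:
    """One local-alignment comparison between two proteins."""

    query_id: str
    subject_id: str
    raw_score: float
    percent_similarity: float
    length_difference_fraction: float
    alignment_length: int = 0
    coverage: float = 0.0

    def qualifies(
        self,
        min_similarity: float = MIN_SIMILARITY,
        max_length_diff: float = MAX_LENGTH_DIFF,
        min_coverage: float = MIN_COVERAGE,
    ) -> bool:
        return (
            self.percent_similarity >= min_similarity
            and self.length_difference_fraction < max_length_diff
            and self.coverage >= min_coverage
        )


def length_difference_fraction(a: str, b: str) -> float:
    """|len(a) − len(b)| / max(len(a), len(b))."""
    return abs(len(a) - len(b)) / max(len(a), len(b))


def align_pair(
    a: str,
    b: str,
    query_id: str = "a",
    subject_id: str = "b",
    mode: str = "positives",
) -> PairwiseHit:
    """Smith-Waterman alignment of two protein sequences.

    percent_similarity = 100 × (positive-scoring aligned pairs) /
    (alignment length including gap columns); ``mode="identity"`` counts
    identical pairs instead.  Deterministic and symmetric in similarity.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if mode not in ("positives", "identity"):
        raise ValueError(f"unknown similarity mode {mode!r}")
    sa, sb = bseq.ProteinSequence(a), bseq.ProteinSequence(b)
    aln = balign.align_optimal(
        sa, sb, _MATRIX, gap_penalty=_GAP_PENALTY, local=True, max_number=1
    )[0]
    trace = aln.trace
    length = trace.shape[0]
    if length == 0:
        return PairwiseHit(query_id, subject_id, 0.0, 0.0, length_difference_fraction(a, b))
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    ca = sa.code[trace[both, 0]]
    cb = sb.code[trace[both, 1]]
    if mode == "positives":
        good = int(np.count_nonzero(_SCORES[ca, cb] > 0))
    else:
        good = int(np.count_nonzero(ca == cb))
    return PairwiseHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=float(aln.score),
        percent_similarity=100.0 * good / length,
        length_difference_fraction=length_difference_fraction(a, b),
        alignment_length=length,
        coverage=int(np.count_nonzero(both)) / min(len(a), len(b)),
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class _KmerIndex:
    """Inverted k-mer index over one proteome, for candidate prefiltering."""

    def __init__(self, proteome: Proteome, k: int):
        self.k = k
        self.index: dict[str, list[str]] = defaultdict(list)
        for pid, seq in proteome.proteins:
            for kmer in _kmers(seq, k):
                self.index[kmer].append(pid)

    def candidates(self, seq: str, min_shared: int) -> list[str]:
        counts: dict[str, int] = defaultdict(int)
        for kmer in _kmers(seq, self.k):
            for pid in self.index.get(kmer, ()):
                counts[pid] += 1
        return [pid for pid, c in counts.items() if c >= min_shared]


@dataclass
class OrthologyParams:
    """Thresholds and aligner settings shared by all orthology calls."""

    min_similarity: float = MIN_SIMILARITY
    max_length_diff: float = MAX_LENGTH_DIFF
    min_coverage: float = MIN_COVERAGE
    similarity_mode: str = "positives"
    prefilter_k: int | None = 4
    prefilter_min_shared: int = 2


def _candidate_map(
    P: Proteome, Q: Proteome, params: OrthologyParams
) -> dict[str, list[str]]:
    """For each protein of P, the Q proteins worth aligning against."""
    if params.prefilter_k is None:
        all_q = Q.protein_ids
        return {pid: all_q for pid in P.protein_ids}
    index = _KmerIndex(Q, params.prefilter_k)
    return {
        pid: index.candidates(seq, params.prefilter_min_shared)
        for pid, seq in P.proteins
    }


def _score_pairs(
    P: Proteome, Q: Proteome, params: OrthologyParams
) -> dict[tuple[str, str], PairwiseHit]:
    """Align every candidate (p, q) pair once; scores are symmetric."""
    cand = _candidate_map(P, Q, params)
    hits: dict[tuple[str, str], PairwiseHit] = {}
    for pid, qids in cand.items():
        seq_p = P.sequence(pid)
        for qid in qids:
            hits[(pid, qid)] = align_pair(
                seq_p, Q.sequence(qid), pid, qid, mode=params.similarity_mode
            )
    return hits


def _best_unique(
    hits: dict[tuple[str, str], PairwiseHit], ids: list[str], axis: int
) -> dict[str, str]:
    """Unique top-scoring partner per protein along one direction.

    Ties on raw score disqualify the protein (no best hit recorded).
    """
    by_query: dict[str, list[PairwiseHit]] = defaultdict(list)
    for (pid, qid), hit in hits.items():
        key = pid if axis == 0 else qid
        by_query[key].append(hit)
    best: dict[str, str] = {}
    for key in ids:
        cand = by_query.get(key)
        if not cand:
            continue
        top = max(h.raw_score for h in cand)
        winners = [h for h in cand if h.raw_score == top]
        if len(winners) == 1:
            h = winners[0]
            best[key] = h.subject_id if axis == 0 else h.query_id
    return best


def reciprocal_best_hits(
    P: Proteome,
    Q: Proteome,
    params: OrthologyParams | None = None,
) -> list[PairwiseHit]:
    """Qualifying reciprocal best hits between two proteomes.

    A pair (p, q) is returned iff q is p's unique top-scoring hit in Q,
    p is q's unique top-scoring hit in P, and the pair's alignment meets
    the similarity / length-difference / coverage thresholds.  Each
    protein appears in at most one pair.
    """
    if P.genome_id == Q.genome_id:
        raise ValueError("reciprocal best hits require two distinct genomes")
    params = params or OrthologyParams()
    hits = _score_pairs(P, Q, params)
    fwd = _best_unique(hits, P.protein_ids, axis=0)
    rev = _best_unique(hits, Q.protein_ids, axis=1)
    out = []
    for pid, qid in fwd.items():
        if rev.get(qid) != pid:
            continue
        hit = hits[(pid, qid)]
        if hit.qualifies(params.min_similarity, params.max_length_diff, params.min_coverage):
            out.append(hit)
    return sorted(out, key=lambda h: (h.query_id, h.subject_id))


@dataclass
class OrthologFamily:
    """A set of proteins across genomes linked by qualifying RBHs."""

    family_id: str
    members: set[tuple[str, str]]  # (genome_id, protein_id)
    presence: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ortholog family cannot be empty")
        if not self.presence:
            counts: dict[str, int] = defaultdict(int)
            for g, _ in self.members:
                counts[g] += 1
            self.presence = dict(counts)

    @property
    def genomes(self) -> set[str]:
        return set(self.presence)

    def __len__(self) -> int:
        return len(self.members)


def build_families(
    proteomes: list[Proteome],
    params: OrthologyParams | None = None,
) -> list[OrthologFamily]:
    """Ortholog families = connected components of the union RBH graph.

    Every protein is represented: proteins with no qualifying reciprocal
    hit anywhere form singleton families.  Family ids are assigned in a
    deterministic order (sorted by the smallest member).
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    ids = [p.genome_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id among proteomes")
    params = params or OrthologyParams()
    graph = nx.Graph()
    for prot in proteomes:
        for pid in prot.protein_ids:
            graph.add_node((prot.genome_id, pid))
    for P, Q in itertools.combinations(proteomes, 2):
        for hit in reciprocal_best_hits(P, Q, params):
            graph.add_edge((P.genome_id, hit.query_id), (Q.genome_id, hit.subject_id))
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    return [
        OrthologFamily(family_id=f"F{i:05d}", members=set(comp))
        for i, comp in enumerate(comps, start=1)
    ]


def core_genome(
    families: list[OrthologFamily],
    proteomes: list[Proteome],
    strict: bool = True,
) -> set[str]:
    """Families present in every genome.

    Strict mode (default) requires exactly one member per genome; relaxed
    mode requires at least one.  The strict core is a subset of the
    relaxed core.
    """
    genomes = {p.genome_id for p in proteomes}
    out = set()
    for fam in families:
        if set(fam.presence) != genomes:
            continue
        if strict and any(c != 1 for c in fam.presence.values()):
            continue
        out.add(fam.family_id)
    return out


def niche_specific(
    families: list[OrthologFamily],
    proteomes: dict[str, Proteome],
    design: CladeDesign,
    clade: str,
    params: OrthologyParams | None = None,
) -> set[str]:
    """Families exclusive to one clade's reference genomes.

    A family is niche-specific for ``clade`` iff it is present in every
    reference genome of that clade and no member protein has *any* hit
    meeting the ortholog thresholds (not necessarily reciprocal-best) in
    any reference genome of the opposite clade.
    """
    params = params or OrthologyParams()
    refs = design.reference(clade)
    other_refs = design.reference(design.other(clade))
    other_proteomes = [proteomes[g] for g in other_refs]
    indexes = (
        {p.genome_id: _KmerIndex(p, params.prefilter_k) for p in other_proteomes}
        if params.prefilter_k is not None
        else None
    )
    out = set()
    for fam in families:
        if not all(fam.presence.get(g, 0) >= 1 for g in refs):
            continue
        if any(g in fam.presence for g in other_refs):
            continue
        if _has_cross_clade_hit(fam, proteomes, other_proteomes, indexes, params):
            continue
        out.add(fam.family_id)
    return out


def _has_cross_clade_hit(fam, proteomes, other_proteomes, indexes, params) -> bool:
    for genome_id, pid in sorted(fam.members):
        seq = proteomes[genome_id].sequence(pid)
        for Q in other_proteomes:
            if indexes is not None:
                cand = indexes[Q.genome_id].candidates(seq, params.prefilter_min_shared)
            else:
                cand = Q.protein_ids
            for qid in cand:
                hit = align_pair(seq, Q.sequence(qid), pid, qid, mode=params.similarity_mode)
                if hit.qualifies(
                    params.min_similarity, params.max_length_diff, params.min_coverage
                ):
                    return True
    return False


@dataclass
class GenomePartition:
    """Disjoint family sets: core, per-clade niche-specific, accessory."""

    core: set[str]
    niche_specific_A: set[str]
    niche_specific_B: set[str]
    accessory: set[str]

    def __post_init__(self) -> None:
        sets = [self.core, self.niche_specific_A, self.niche_specific_B, self.accessory]
        for s, t in itertools.combinations(sets, 2):
            if s & t:
                raise ValueError(f"partition sets overlap: {sorted(s & t)[:5]}")


def partition_families(
    families: list[OrthologFamily],
    proteomes: dict[str, Proteome],
    design: CladeDesign,
    strict_core: bool = True,
    params: OrthologyParams | None = None,
) -> GenomePartition:
    """Derive core / niche-specific-A / niche-specific-B / accessory sets."""
    clade_a, clade_b = design.clade_labels[:2]
    core = core_genome(families, list(proteomes.values()), strict=strict_core)
    spec_a = niche_specific(families, proteomes, design, clade_a, params) - core
    spec_b = niche_specific(families, proteomes, design, clade_b, params) - core - spec_a
    all_ids = {f.family_id for f in families}
    return GenomePartition(
        core=core,
        niche_specific_A=spec_a,
        niche_specific_B=spec_b,
        accessory=all_ids - core - spec_a - spec_b,
    )


def report_percentage(hypothetical: int, total: int) -> int:
    """Integer percentage as printed in reports: round(100·k/n) to nearest."""
    if total <= 0:
        raise ValueError("set size must be positive")
    return int(round(100.0 * hypothetical / total))


def summarize_partition(
    partition: GenomePartition,
    families: list[OrthologFamily],
    hypothetical_flags: dict[tuple[str, str], bool],
) -> dict[str, dict]:
    """Count hypothetical-protein content of each partition set.

    A family is counted as hypothetical when at least half of its member
    proteins are flagged.  Returns, per set, the family count, the
    hypothetical count, the raw fraction and the rounded integer
    percentage used in reports.
    """
    by_id = {f.family_id: f for f in families}
    report = {}
    for name in ("core", "niche_specific_A", "niche_specific_B", "accessory"):
        ids = getattr(partition, name)
        n_hypo = 0
        for fid in ids:
            fam = by_id[fid]
            missing = [m for m in fam.members if m not in hypothetical_flags]
            if missing:
                raise ValueError(f"hypothetical flag missing for {missing[0]}")
            flagged = sum(hypothetical_flags[m] for m in fam.members)
            if 2 * flagged >= len(fam.members):
                n_hypo += 1
        entry = {"size": len(ids), "hypothetical": n_hypo}
        if ids:
            entry["fraction"] = n_hypo / len(ids)
            entry["percent"] = report_percentage(n_hypo, len(ids))
        report[name] = entry
    return report
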