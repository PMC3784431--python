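import numpy as np
import pytest

from nichecomp.io_model import AMINO_ACIDS, Proteome
from nichecomp.orthology import (
    OrthologyParams,
    align_pair,
    build_families,
    core_genome,
    length_difference_fraction,
    niche_specific,
    partition_families,
    reciprocal_best_hits,
    report_percentage,
    summarize_partition,
)
from nichecomp.synthetic import SimulationConfig, generate, hypothetical_flags, mutate

from _reference import sw_score


class TestAlignPair:
    def test_identical_sequences_are_fully_similar(self):
        hit = align_pair("MKVLAWCDEF", "MKVLAWCDEF")
        assert hit.percent_similarity == 100.0
        assert hit.length_difference_fraction == 0.0
        assert hit.coverage == 1.0

    def test_similarity_is_symmetric(self):
        a, b = "ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLWWPQRSTVWY"
        assert align_pair(a, b).percent_similarity == align_pair(b, a).percent_similarity

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKV")

    def test_length_difference_uses_longer_as_denominator(self):
        assert length_difference_fraction("A" * 100, "C" * 60) == pytest.approx(0.4)

    def test_scores_match_naive_dynamic_programming(self):
        """Smith-Waterman oracle: 200 random short pairs, exact score equality."""
        rng = np.random.default_rng(42)
        alphabet = list(AMINO_ACIDS + "X")
        for _ in range(200):
            la, lb = rng.integers(1, 31, size=2)
            a = "".join(rng.choice(alphabet, la))
            b = "".join(rng.choice(alphabet, lb))
            assert align_pair(a, b).raw_score == sw_score(a, b)

    def test_reversed_disjoint_control_scored_by_oracle(self):
        a = "ACDEFGHIKL"
        b = a[::-1]
        hit = align_pair(a, b)
        assert hit.raw_score == sw_score(a, b)
        # only a noise-level local island aligns between a and its reversal
        assert hit.coverage < 0.5

    def test_identity_mode_is_at_most_positives_mode(self):
        a, b = "MKVLAWCDEFGHIKNPQRST", mutate("MKVLAWCDEFGHIKNPQRST", 0.3, 5)
        pos = align_pair(a, b, mode="positives").percent_similarity
        ident = align_pair(a, b, mode="identity").percent_similarity
        assert ident <= pos


def _proteome(genome_id, seqs):
    return Proteome(genome_id, [(f"{genome_id}_p{i}", s) for i, s in enumerate(seqs)])


class TestReciprocalBestHits:
    def test_identity_proteomes_pair_every_protein(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 60)) for _ in range(5)]
        P, Q = _proteome("P", seqs), _proteome("Q", seqs)
        pairs = reciprocal_best_hits(P, Q)
        assert {(h.query_id, h.subject_id) for h in pairs} == {
            (f"P_p{i}", f"Q_p{i}") for i in range(5)
        }

    def test_exact_score_tie_disqualifies_query(self):
        rng = np.random.default_rng(1)
        s = "".join(rng.choice(list(AMINO_ACIDS), 60))
        P = _proteome("P", [s])
        Q = _proteome("Q", [s, s])  # two identical best hits: not unique
        assert reciprocal_best_hits(P, Q) == []

    def test_symmetry_under_role_swap(self):
        rng = np.random.default_rng(2)
        base = ["".join(rng.choice(list(AMINO_ACIDS), 70)) for _ in range(6)]
        P = _proteome("P", base)
        Q = _proteome("Q", [mutate(s, 0.1, i) for i, s in enumerate(base)])
        fwd = {(h.query_id, h.subject_id) for h in reciprocal_best_hits(P, Q)}
        rev = {(h.subject_id, h.query_id) for h in reciprocal_best_hits(Q, P)}
        assert fwd == rev and fwd

    def test_planted_pair_recovered_at_low_divergence_rejected_at_high(self):
        rng = np.random.default_rng(3)
        anc = "".join(rng.choice(list(AMINO_ACIDS), 200))
        near = _proteome("P", [mutate(anc, 0.1, 11)])
        far = _proteome("R", [mutate(anc, 0.5, 13)])
        Q = _proteome("Q", [mutate(anc, 0.1, 12)])
        assert len(reciprocal_best_hits(near, Q)) == 1
        # ~50% divergence on both copies pushes similarity below 60%
        assert reciprocal_best_hits(far, _proteome("S", [mutate(anc, 0.5, 14)])) == []

    def test_same_genome_rejected(self):
        P = _proteome("P", ["MKVLAW" * 5])
        with pytest.raises(ValueError):
            reciprocal_best_hits(P, P)


class TestFamiliesAndPartition:
    def test_identical_proteomes_give_one_family_per_protein(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 60)) for _ in range(5)]
        proteomes = [_proteome(g, seqs) for g in "XYZ"]
        fams = build_families(proteomes)
        assert len(fams) == 5
        assert all(len(f) == 3 for f in fams)
        assert len(core_genome(fams, proteomes, strict=True)) == 5
        assert len(core_genome(fams, proteomes, strict=False)) == 5

    def test_protein_without_hits_forms_singleton_family(self):
        rng = np.random.default_rng(5)
        shared = "".join(rng.choice(list(AMINO_ACIDS), 80))
        lone = "".join(rng.choice(list(AMINO_ACIDS), 80))
        P = _proteome("P", [shared, lone])
        Q = _proteome("Q", [shared])
        fams = build_families([P, Q])
        sizes = sorted(len(f) for f in fams)
        assert sizes == [1, 2]

    def test_two_member_genome_family_excluded_from_strict_core_only(self):
        rng = np.random.default_rng(6)
        s = "".join(rng.choice(list(AMINO_ACIDS), 80))
        # P carries two near-identical copies: the family keeps presence 2
        P = Proteome("P", [("P_a", s), ("P_b", mutate(s, 0.02, 1))])
        Q = Proteome("Q", [("Q_a", mutate(s, 0.05, 2))])
        fams = build_families([P, Q])
        fam = max(fams, key=len)
        if fam.presence.get("P") == 2:  # both copies joined the component
            assert core_genome(fams, [P, Q], strict=True) == set()
            assert fam.family_id in core_genome(fams, [P, Q], strict=False)

    def test_planted_counts_recovered(self, small_dataset, small_families):
        cfg = small_dataset.config
        part = partition_families(
            small_families, small_dataset.proteomes, small_dataset.design
        )
        assert len(part.core) == cfg.n_core
        assert len(part.niche_specific_A) == cfg.n_specific_A
        assert len(part.niche_specific_B) == cfg.n_specific_B

    def test_partition_sets_are_pairwise_disjoint(self, small_dataset, small_families):
        part = partition_families(
            small_families, small_dataset.proteomes, small_dataset.design
        )
        sets = [part.core, part.niche_specific_A, part.niche_specific_B, part.accessory]
        assert sum(map(len, sets)) == len({x for s in sets for x in s})

    def test_raising_similarity_threshold_never_enlarges_sets(self, small_dataset):
        proteomes = list(small_dataset.proteomes.values())
        loose = build_families(proteomes, OrthologyParams(min_similarity=60))
        tight = build_families(proteomes, OrthologyParams(min_similarity=85))
        core_loose = core_genome(loose, proteomes)
        core_tight = core_genome(tight, proteomes)
        assert len(core_tight) <= len(core_loose)
        ns_loose = niche_specific(
            loose, small_dataset.proteomes, small_dataset.design, "A",
            OrthologyParams(min_similarity=60),
        )
        ns_tight = niche_specific(
            tight, small_dataset.proteomes, small_dataset.design, "A",
            OrthologyParams(min_similarity=85),
        )
        assert len(ns_tight) <= len(ns_loose)

    def test_cross_clade_homolog_falsifies_specificity(self):
        rng = np.random.default_rng(8)
        anc = "".join(rng.choice(list(AMINO_ACIDS), 120))
        other = "".join(rng.choice(list(AMINO_ACIDS), 120))
        # family in both A genomes; B genome carries a 90%-similar homolog
        A1 = Proteome("A1", [("A1_p1", mutate(anc, 0.05, 1))], clade="A")
        A2 = Proteome("A2", [("A2_p1", mutate(anc, 0.05, 2))], clade="A")
        B1 = Proteome("B1", [("B1_p1", mutate(anc, 0.08, 3)), ("B1_p2", other)], clade="B")
        from nichecomp.io_model import CladeDesign

        design = CladeDesign(clades={"A1": "A", "A2": "A", "B1": "B"})
        proteomes = {"A1": A1, "A2": A2, "B1": B1}
        fams = build_families([A1, A2, B1])
        specific = niche_specific(fams, proteomes, design, "A")
        a_fams = [f.family_id for f in fams if ("A1", "A1_p1") in f.members]
        assert not (set(a_fams) & specific)


class TestSummaries:
    @pytest.mark.parametrize(
        "hypothetical,total,expected",
        [(18, 32, 56), (315, 798, 39), (9, 227, 4)],
    )
    def test_reported_percentages_round_to_nearest_integer(
        self, hypothetical, total, expected
    ):
        assert report_percentage(hypothetical, total) == expected

    def test_summarize_counts_hypothetical_families(self, small_dataset, small_families):
        part = partition_families(
            small_families, small_dataset.proteomes, small_dataset.design
        )
        report = summarize_partition(part, small_families, hypothetical_flags(small_dataset))
        assert report["core"]["size"] == small_dataset.config.n_core
        for entry in report.values():
            assert 0 <= entry["hypothetical"] <= entry["size"]
            if entry["size"]:
                assert entry["percent"] == round(100 * entry["fraction"])
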