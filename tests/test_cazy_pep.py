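import math

import numpy as np
import pandas as pd
import pytest

from nichecomp.cazy_pep import (
    FamilyCountMatrix,
    clade_unique_families,
    consensus_annotation,
    family_class,
    family_matrix,
    lifestyle_ratio,
    load_flavobacterium_counts,
    shannon,
    shannon_by_genome,
)
from nichecomp.io_model import CladeDesign
from nichecomp.synthetic import SimulationConfig, generate


def _predictions(rows):
    return pd.DataFrame(rows, columns=["genome_id", "protein_id", "family", "source"])


class TestConsensus:
    def test_agreement_retained_disagreement_dropped(self):
        preds = _predictions(
            [
                ("g", "p1", "GH78", "src1"),
                ("g", "p1", "GH78", "src2"),
                ("g", "p2", "GH78", "src1"),
                ("g", "p2", "GH106", "src2"),
                ("g", "p3", "GH43", "src1"),  # only one source
            ]
        )
        cons = consensus_annotation(preds, mode="family")
        assert list(map(tuple, cons.itertuples(index=False))) == [("g", "p1", "GH78")]

    def test_class_mode_keeps_same_class_disagreements(self):
        preds = _predictions(
            [("g", "p2", "GH78", "src1"), ("g", "p2", "GH106", "src2")]
        )
        cons = consensus_annotation(preds, mode="class")
        assert list(cons["family"]) == ["GH"]

    def test_multiplicity_preserved(self):
        # two GH43 domains predicted by both sources count twice
        preds = _predictions(
            [("g", "p1", "GH43", "src1")] * 2 + [("g", "p1", "GH43", "src2")] * 2
        )
        cons = consensus_annotation(preds)
        assert len(cons) == 2

    def test_family_consensus_projects_into_class_consensus(self):
        rng = np.random.default_rng(0)
        fams = ["GH78", "GH106", "CE2", "S8", "M16"]
        rows = []
        for i in range(60):
            f1, f2 = rng.choice(fams, 2)
            rows += [("g", f"p{i}", f1, "src1"), ("g", f"p{i}", f2, "src2")]
        preds = _predictions(rows)
        by_family = consensus_annotation(preds, "family")
        by_class = consensus_annotation(preds, "class")
        fam_as_class = {
            (g, p, family_class(f)) for g, p, f in by_family.itertuples(index=False)
        }
        class_set = set(map(tuple, by_class.itertuples(index=False)))
        assert fam_as_class <= class_set

    def test_wrong_source_count_rejected(self):
        with pytest.raises(ValueError, match="2 sources"):
            consensus_annotation(_predictions([("g", "p1", "GH78", "only")]))


class TestFamilyMatrix:
    def test_counts_agreed_assignments(self):
        cons = pd.DataFrame(
            [("g1", f"p{i}", "GH18") for i in range(3)],
            columns=["genome_id", "protein_id", "family"],
        )
        m = family_matrix(cons, genomes=["g1", "g2"])
        assert m.counts.loc["g1", "GH18"] == 3
        assert m.counts.loc["g2", "GH18"] == 0

    def test_empty_consensus_gives_all_zero_matrix(self):
        m = family_matrix(pd.DataFrame(columns=["genome_id", "protein_id", "family"]),
                          genomes=["g1"])
        assert m.counts.empty or not m.counts.to_numpy().any()

    def test_planted_counts_recovered(self, small_dataset):
        cons = consensus_annotation(small_dataset.predictions)
        m = family_matrix(cons, genomes=list(small_dataset.proteomes))
        truth = pd.DataFrame(
            small_dataset.truth.enzyme_assignments,
            columns=["genome_id", "protein_id", "family"],
        )
        expected = truth.groupby(["genome_id", "family"]).size()
        for (g, fam), n in expected.items():
            assert m.counts.loc[g, fam] == n


class TestCladeUnique:
    @pytest.fixture()
    def toy(self):
        counts = pd.DataFrame(
            {
                "GH78": [2, 1, 3, 1, 0, 0, 0],
                "GH13": [4, 2, 1, 3, 2, 5, 1],
                "GH95": [1, 1, 0, 0, 0, 1, 0],  # one aquatic count: not unique
            },
            index=[f"t{i}" for i in range(5)] + ["q1", "q2"],
        )
        design = CladeDesign(
            clades={g: ("T" if g.startswith("t") else "Q") for g in counts.index}
        )
        return FamilyCountMatrix(counts, {f: "GH" for f in counts}), design

    def test_presence_and_absence_rule(self, toy):
        matrix, design = toy
        uniq = clade_unique_families(matrix, design, "T", presence_fraction=0.5)
        assert "GH78" in uniq  # 4/5 terrestrial, absent from aquatic
        assert "GH13" not in uniq  # present in aquatic
        assert "GH95" not in uniq  # single aquatic count falsifies uniqueness

    def test_monotone_in_presence_fraction(self, toy):
        matrix, design = toy
        lo = clade_unique_families(matrix, design, "T", presence_fraction=0.4)
        hi = clade_unique_families(matrix, design, "T", presence_fraction=0.9)
        assert hi <= lo

    def test_published_flavobacterium_markers(self):
        """The rhamnogalacturonan families GH78/GH106 are terrestrial-unique
        in the published 15-strain count table; GH130 is not (one aquatic
        strain carries it)."""
        matrix, design = load_flavobacterium_counts()
        uniq = clade_unique_families(matrix, design, "terrestrial", 0.5)
        assert {"GH78", "GH106"} <= uniq
        assert "GH130" not in uniq
        assert "GH28" not in uniq  # one aquatic genome carries GH28


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5, 5], math.log(4)),
            ([10, 0, 0], 0.0),
            ([7, 3], 0.6109),
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_bounded_by_log_richness_and_maximized_at_uniform(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            c = rng.integers(0, 30, size=8)
            if c.sum() == 0:
                continue
            h = shannon(c)
            k = int((c > 0).sum())
            assert 0 <= h <= math.log(k) + 1e-12
        assert shannon([3, 3, 3]) == pytest.approx(math.log(3))

    def test_class_level_at_most_family_level_for_flavobacteria(self):
        matrix, _ = load_flavobacterium_counts()
        fam = shannon_by_genome(matrix, "family")
        cls = shannon_by_genome(matrix, "class")
        common = fam.index.intersection(cls.index)
        assert (cls[common] <= fam[common] + 1e-12).all()


class TestLifestyleRatio:
    def _matrix(self, rows, genomes):
        counts = pd.DataFrame(rows, index=genomes, columns=["S8", "GH13"])
        return FamilyCountMatrix(counts, {"S8": "PEP", "GH13": "GH"})

    def test_simple_arithmetic(self):
        m = self._matrix([[100, 6]], ["g1"])
        design = CladeDesign(clades={"g1": "A", "x": "B"}, references={"A": {"g1"}, "B": {"x"}})
        rep = lifestyle_ratio(m, design)
        assert rep.per_genome.iloc[0]["ratio"] == pytest.approx(100 / 6, abs=1e-9)

    def test_constant_ratios_give_zero_sd(self):
        m = self._matrix([[4, 2]] * 3, ["g1", "g2", "g3"])
        design = CladeDesign(
            clades={"g1": "A", "g2": "A", "g3": "A", "x": "B"},
            references={"A": {"g1", "g2", "g3"}, "B": {"x"}},
        )
        clade_a = rep = lifestyle_ratio(m, design).per_clade.set_index("clade").loc["A"]
        assert clade_a["mean"] == pytest.approx(2.0)
        assert clade_a["sd"] == pytest.approx(0.0)

    def test_zero_gh_flagged_and_excluded_from_mean(self):
        m = self._matrix([[5, 0], [4, 2]], ["g1", "g2"])
        design = CladeDesign(
            clades={"g1": "A", "g2": "A", "x": "B"},
            references={"A": {"g1", "g2"}, "B": {"x"}},
        )
        rep = lifestyle_ratio(m, design)
        assert bool(rep.per_genome.set_index("genome_id").loc["g1", "flagged"])
        clade_a = rep.per_clade.set_index("clade").loc["A"]
        assert clade_a["n"] == 1 and clade_a["mean"] == pytest.approx(2.0)

    def test_planted_clade_ratios_recovered(self):
        ds = generate(SimulationConfig(seed=11, n_genomes_A=5, n_genomes_B=5))
        m = family_matrix(
            consensus_annotation(ds.predictions), genomes=list(ds.proteomes)
        )
        rep = lifestyle_ratio(m, ds.design).per_clade.set_index("clade")
        assert rep.loc["A", "mean"] == pytest.approx(1.7, abs=0.5)
        assert rep.loc["B", "mean"] == pytest.approx(9.7, abs=0.5)

    def test_duplicating_every_genome_preserves_clade_means(self):
        m = self._matrix([[6, 3], [10, 2]], ["g1", "g2"])
        dup = FamilyCountMatrix(
            pd.concat([m.counts, m.counts.rename(index=lambda g: g + "_copy")]),
            m.classes,
        )
        design1 = CladeDesign(clades={"g1": "A", "g2": "A", "x": "B"},
                              references={"A": {"g1", "g2"}, "B": {"x"}})
        design2 = CladeDesign(
            clades={"g1": "A", "g2": "A", "g1_copy": "A", "g2_copy": "A", "x": "B"},
            references={"A": {"g1", "g2"}, "B": {"x"}},
        )
        m1 = lifestyle_ratio(m, design1).per_clade.set_index("clade").loc["A", "mean"]
        m2 = lifestyle_ratio(dup, design2).per_clade.set_index("clade").loc["A", "mean"]
        assert m1 == pytest.approx(m2)

    def test_missing_classes_rejected(self):
        counts = pd.DataFrame([[3]], index=["g1"], columns=["GH13"])
        m = FamilyCountMatrix(counts, {"GH13": "GH"})
        design = CladeDesign(clades={"g1": "A", "x": "B"}, references={"A": {"g1"}, "B": {"x"}})
        with pytest.raises(ValueError, match="PEP"):
            lifestyle_ratio(m, design)
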