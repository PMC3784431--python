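"""Clade-structured synthetic pangenomes with planted truth.

The generator emulates the study design the pipeline targets: two clades
of bacterial genomes (clade A terrestrial-like, glycan-centric; clade B
aquatic-like, peptide-centric) whose proteomes contain

* a shared *core* of gene families present in every genome,
* clade-specific families present in every genome of one clade only,
* per-genome *private* singleton families,

all diverged from per-family ancestral sequences by independent point
substitutions at a configurable rate.  Functional labels (SEED-style
category/subsystem) are drawn per protein from clade-biased category
distributions, and CAZy / peptidase family assignments are planted so
each genome realizes a clade-typical peptidase/GH ratio.  Every planted
fact is returned as a machine-readable truth set so recovery by the
analysis stages can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import AMINO_ACIDS, CladeDesign, Proteome, write_design, write_proteome

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

#: default clade-biased SEED-style category distributions.  Clade A
#: (terrestrial-like) is carbohydrate-rich, clade B (aquatic-like) is
#: protein-metabolism-rich; the remaining mass is shared housekeeping.
DEFAULT_PROFILES = {
    "A": {
        "Carbohydrates": 0.28,
        "Protein Metabolism": 0.08,
        "Amino Acids and Derivatives": 0.14,
        "Cofactors and Vitamins": 0.10,
        "Membrane Transport": 0.12,
        "Stress Response": 0.08,
        "Hypothetical": 0.20,
    },
    "B": {
        "Carbohydrates": 0.10,
        "Protein Metabolism": 0.24,
        "Amino Acids and Derivatives": 0.14,
        "Cofactors and Vitamins": 0.10,
        "Membrane Transport": 0.12,
        "Stress Response": 0.10,
        "Hypothetical": 0.20,
    },
}

#: GH family pools; the first two clade-A families are the terrestrial
#: marker families (rhamnogalacturonan utilization) absent from clade B
GH_POOL_A = ["GH78", "GH106", "GH43", "GH10", "GH13", "GH2", "GH3", "GH29"]
GH_POOL_B = ["GH13", "GH2", "GH3", "GH20", "GH23"]
PEP_POOL = ["S8", "M16", "C25", "M14", "S41", "S9"]
OTHER_CAZY_POOL = ["CE1", "CE4", "GT2", "GT4", "CBM6"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic pangenome.

    Defaults emulate the real study at reduced scale: a terrestrial-like
    clade A of 4 genomes and an aquatic-like clade B of 3 (the study used
    8 + 7), a core much smaller than the clade-specific complement of the
    larger-genomed clade, sequence divergence 0.15 (comfortably inside
    the 60%-similarity ortholog threshold), and planted peptidase/GH
    ratios 1.7 (A) vs 9.7 (B), the study's lifestyle contrast.
    """

    n_genomes_A: int = 4
    n_genomes_B: int = 3
    n_core: int = 50
    n_specific_A: int = 20
    n_specific_B: int = 10
    n_private_per_genome: int = 5
    divergence: float = 0.15
    mean_protein_length: float = 120.0
    sd_protein_length: float = 25.0
    min_protein_length: int = 40
    clade_function_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROFILES.items()}
    )
    planted_pep_gh_ratio_A: float = 1.7
    planted_pep_gh_ratio_B: float = 9.7
    gh_mean_A: float = 30.0
    gh_mean_B: float = 8.0
    ratio_noise_sd: float = 0.3
    other_cazy_mean: float = 4.0
    disagreement_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_genomes_A,
            self.n_genomes_B,
            self.n_core,
            self.n_specific_A,
            self.n_specific_B,
            self.n_private_per_genome,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_genomes_A < 1 or self.n_genomes_B < 1:
            raise ValueError("each clade needs at least one genome")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")
        if not 0 <= self.disagreement_rate <= 1:
            raise ValueError("disagreement_rate must be in [0, 1]")
        if self.planted_pep_gh_ratio_A <= 0 or self.planted_pep_gh_ratio_B <= 0:
            raise ValueError("planted ratios must be positive")
        if self.gh_mean_A <= 0 or self.gh_mean_B <= 0:
            raise ValueError("a positive GH mean is required for a finite pep/GH ratio")
        for clade, prof in self.clade_function_profiles.items():
            total = sum(prof.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"clade {clade!r} category distribution sums to {total}")


@dataclass
class TruthSet:
    """Planted ground truth for one generated dataset."""

    family_roles: dict[str, str]  # family_id -> core|specific_A|specific_B|private
    protein_family: dict[tuple[str, str], str]  # (genome, protein) -> family_id
    protein_category: dict[tuple[str, str], str]
    enzyme_assignments: list[tuple[str, str, str]]  # (genome, protein, family)

    def families_with_role(self, role: str) -> set[str]:
        return {f for f, r in self.family_roles.items() if r == role}


@dataclass
class SimulatedDataset:
    """Everything one simulator run produces."""

    proteomes: dict[str, Proteome]
    annotations: pd.DataFrame
    predictions: pd.DataFrame  # both sources, distinguished by the source column
    design: CladeDesign
    truth: TruthSet
    config: SimulationConfig


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def mutate(sequence: str, divergence: float, rng: np.random.Generator | int) -> str:
    """Point-substitute each position independently with probability ``divergence``.

    Substitutions are drawn uniformly from the 19 alternative residues, so
    the expected Hamming distance is divergence × length and length is
    always preserved.
    """
    if not sequence:
        raise ValueError("cannot mutate an empty sequence")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer(sequence.encode(), dtype="S1").astype("U1")
    hit = rng.random(arr.size) < divergence
    n_hit = int(hit.sum())
    if n_hit:
        current = arr[hit]
        # uniform over the 19 alternatives: draw an offset 1..19 in the
        # alphabet ordering relative to the current residue
        idx = np.searchsorted(_AA, current)
        offsets = rng.integers(1, len(_AA), size=n_hit)
        arr[hit] = _AA[(idx + offsets) % len(_AA)]
    return "".join(arr)


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Optional geometric-length indels, used to exercise the length filter."""
    out = []
    i = 0
    while i < len(seq):
        if rng.random() < rate:
            length = rng.geometric(0.5)
            if rng.random() < 0.5:
                i += length  # deletion
                continue
            out.append(_random_sequence(rng, length))  # insertion
        out.append(seq[i])
        i += 1
    return "".join(out) or seq


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset; bit-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    genomes_a = [f"A{i + 1:02d}" for i in range(config.n_genomes_A)]
    genomes_b = [f"B{i + 1:02d}" for i in range(config.n_genomes_B)]
    clade_of = {g: "A" for g in genomes_a} | {g: "B" for g in genomes_b}
    design = CladeDesign(clades=clade_of)
    all_genomes = genomes_a + genomes_b

    # ---- plant families ------------------------------------------------
    fams: list[tuple[str, str, list[str]]] = []  # (family_id, role, member genomes)
    fid = 0
    for _ in range(config.n_core):
        fid += 1
        fams.append((f"T{fid:05d}", "core", all_genomes))
    for _ in range(config.n_specific_A):
        fid += 1
        fams.append((f"T{fid:05d}", "specific_A", genomes_a))
    for _ in range(config.n_specific_B):
        fid += 1
        fams.append((f"T{fid:05d}", "specific_B", genomes_b))
    for g in all_genomes:
        for _ in range(config.n_private_per_genome):
            fid += 1
            fams.append((f"T{fid:05d}", "private", [g]))

    proteins: dict[str, list[tuple[str, str]]] = {g: [] for g in all_genomes}
    protein_family: dict[tuple[str, str], str] = {}
    family_roles: dict[str, str] = {}
    for family_id, role, members in fams:
        family_roles[family_id] = role
        length = max(
            config.min_protein_length,
            int(round(rng.normal(config.mean_protein_length, config.sd_protein_length))),
        )
        ancestral = _random_sequence(rng, length)
        for g in members:
            seq = mutate(ancestral, config.divergence, rng)
            if config.indel_rate > 0:
                seq = _apply_indels(seq, config.indel_rate, rng)
            pid = f"{g}_p{len(proteins[g]) + 1:04d}"
            proteins[g].append((pid, seq))
            protein_family[(g, pid)] = family_id

    proteomes = {
        g: Proteome(genome_id=g, proteins=plist, clade=clade_of[g])
        for g, plist in proteins.items()
    }

    # ---- functional labels --------------------------------------------
    ann_rows = []
    protein_category: dict[tuple[str, str], str] = {}
    for g in all_genomes:
        prof = config.clade_function_profiles[clade_of[g]]
        cats = list(prof)
        probs = np.array([prof[c] for c in cats])
        draws = rng.choice(len(cats), size=len(proteins[g]), p=probs)
        for (pid, _), ci in zip(proteins[g], draws):
            cat = cats[ci]
            sub = f"{cat} | subsystem {int(rng.integers(1, 3))}"
            ann_rows.append((g, pid, cat, sub, "simulated"))
            protein_category[(g, pid)] = cat
    annotations = pd.DataFrame(
        ann_rows,
        columns=["genome_id", "protein_id", "level1_category", "level2_subsystem", "source"],
    )

    # ---- enzyme families ----------------------------------------------
    pred_rows = []
    enzyme_assignments = []
    all_families_pool = sorted(set(GH_POOL_A + GH_POOL_B + PEP_POOL + OTHER_CAZY_POOL))
    for g in all_genomes:
        clade = clade_of[g]
        gh_pool = GH_POOL_A if clade == "A" else GH_POOL_B
        ratio = (
            config.planted_pep_gh_ratio_A if clade == "A" else config.planted_pep_gh_ratio_B
        )
        gh_mean = config.gh_mean_A if clade == "A" else config.gh_mean_B
        n_gh = max(1, int(rng.poisson(gh_mean)))
        noisy_ratio = max(0.1, ratio + rng.normal(0.0, config.ratio_noise_sd))
        n_pep = max(0, int(round(noisy_ratio * n_gh)))
        n_other = int(rng.poisson(config.other_cazy_mean))
        planted = (
            [str(rng.choice(gh_pool)) for _ in range(n_gh)]
            + [str(rng.choice(PEP_POOL)) for _ in range(n_pep)]
            + [str(rng.choice(OTHER_CAZY_POOL)) for _ in range(n_other)]
        )
        pids = [pid for pid, _ in proteins[g]]
        carriers = rng.choice(len(pids), size=len(planted), replace=True)
        planted_by_protein: dict[str, set[str]] = {}
        for fam, ci in zip(planted, carriers):
            planted_by_protein.setdefault(pids[ci], set()).add(fam)
        for fam, ci in zip(planted, carriers):
            pid = pids[ci]
            enzyme_assignments.append((g, pid, fam))
            pred_rows.append((g, pid, fam, "src1"))
            if rng.random() < config.disagreement_rate:
                # a disagreeing call must not coincide with any family the
                # first source assigns this protein, or the "both methods
                # agree" consensus would retain it by accident
                options = [
                    f for f in all_families_pool if f not in planted_by_protein[pid]
                ]
                alt = str(rng.choice(options or [fam]))
                pred_rows.append((g, pid, alt, "src2"))
            else:
                pred_rows.append((g, pid, fam, "src2"))
    predictions = pd.DataFrame(
        pred_rows, columns=["genome_id", "protein_id", "family", "source"]
    )

    dataset = SimulatedDataset(
        proteomes=proteomes,
        annotations=annotations,
        predictions=predictions,
        design=design,
        truth=TruthSet(
            family_roles=family_roles,
            protein_family=protein_family,
            protein_category=protein_category,
            enzyme_assignments=enzyme_assignments,
        ),
        config=config,
    )
    _check_clade_separation(dataset)
    return dataset


def _check_clade_separation(dataset: SimulatedDataset) -> None:
    """Planted clade structure must separate clades in Bray-Curtis space.

    When the two clade category distributions differ, the mean
    between-clade Bray-Curtis distance over level-1 profiles must exceed
    the mean within-clade distance; violated only by pathological
    configs, and then loudly.
    """
    from .cluster_ordination import bray_curtis_matrix
    from .profiles import build_profiles

    cfg = dataset.config
    if cfg.clade_function_profiles["A"] == cfg.clade_function_profiles["B"]:
        return
    if cfg.n_genomes_A < 2 or cfg.n_genomes_B < 2:
        return
    prof = build_profiles(dataset.annotations, dataset.proteomes, level=1)
    dm = bray_curtis_matrix(prof)
    labels = dm.labels
    within, between = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            same = dataset.design.clades[labels[i]] == dataset.design.clades[labels[j]]
            (within if same else between).append(dm.values[i, j])
    if np.mean(between) <= np.mean(within):
        raise RuntimeError(
            "planted clade structure failed to separate clades in Bray-Curtis space"
        )


def hypothetical_flags(dataset: SimulatedDataset) -> dict[tuple[str, str], bool]:
    """Planted hypothetical-protein flags (category == 'Hypothetical')."""
    return {
        key: cat == "Hypothetical" for key, cat in dataset.truth.protein_category.items()
    }


def planted_two_clade_profiles(
    n_per_clade: int = 5,
    n_categories: int = 30,
    n_informative: int = 15,
    effect_sds: float = 3.0,
    base_mean: float = 0.05,
    noise_sd: float = 0.008,
    seed: int | None = None,
) -> tuple[pd.DataFrame, CladeDesign]:
    """Gaussian two-clade profile matrix with a planted mean shift.

    ``n_informative`` categories are shifted between clades by
    ``effect_sds`` pooled standard deviations; the rest are pure noise.
    Used to exercise clustering, bootstrap support and the clade t-test
    under a known effect size.
    """
    if n_informative > n_categories:
        raise ValueError("n_informative cannot exceed n_categories")
    rng = np.random.default_rng(seed)
    genomes = [f"A{i + 1:02d}" for i in range(n_per_clade)] + [
        f"B{i + 1:02d}" for i in range(n_per_clade)
    ]
    x = rng.normal(base_mean, noise_sd, size=(2 * n_per_clade, n_categories))
    x[:n_per_clade, :n_informative] += effect_sds * noise_sd
    x = np.clip(x, 1e-6, None)
    profiles = pd.DataFrame(
        x, index=genomes, columns=[f"cat{j + 1:02d}" for j in range(n_categories)]
    )
    design = CladeDesign(
        clades={g: ("A" if g.startswith("A") else "B") for g in genomes}
    )
    return profiles, design


def planted_configuration(
    n_points: int = 12, k: int = 2, scale: float = 1.0, seed: int | None = None
):
    """Random k-D point configuration and its exact Euclidean distances.

    Returns (coordinates, DistanceMatrix); used to validate nMDS recovery.
    """
    from scipy.spatial.distance import pdist, squareform

    from .cluster_ordination import DistanceMatrix

    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, scale, size=(n_points, k))
    labels = [f"g{i + 1:02d}" for i in range(n_points)]
    dm = DistanceMatrix(labels=labels, values=squareform(pdist(coords)))
    return coords, dm


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA per genome plus all tables; returns name → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for g, prot in sorted(dataset.proteomes.items()):
        p = outdir / f"{g}.faa"
        write_proteome(prot, p)
        paths[f"proteome_{g}"] = p
    paths["annotations"] = outdir / "annotations.tsv"
    dataset.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    for src in sorted(dataset.predictions["source"].unique()):
        p = outdir / f"predictions_{src}.tsv"
        dataset.predictions[dataset.predictions["source"] == src].to_csv(
            p, sep="\t", index=False
        )
        paths[f"predictions_{src}"] = p
    paths["design"] = outdir / "design.tsv"
    write_design(dataset.design, paths["design"])
    paths["truth"] = outdir / "truth.tsv"
    truth_rows = [
        (g, pid, fam, dataset.truth.family_roles[fam], dataset.truth.protein_category[(g, pid)])
        for (g, pid), fam in sorted(dataset.truth.protein_family.items())
    ]
    pd.DataFrame(
        truth_rows, columns=["genome_id", "protein_id", "family_id", "role", "category"]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
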