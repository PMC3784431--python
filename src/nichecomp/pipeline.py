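"""End-to-end orchestration: simulate → orthology → profiles → cluster →
enzyme accounting → enrichment, with a manifest and reproducible seeds.

Every stage is also runnable standalone (see :mod:`nichecomp.cli`); the
pipeline simply wires defaults together, writes each stage's artifacts
under a run directory, and records a manifest whose config hash is stable
under key reordering, so a rerun with the same config reproduces
identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cazy_pep import (
    clade_unique_families,
    consensus_annotation,
    family_matrix,
    lifestyle_ratio,
    shannon_by_genome,
)
from .cluster_ordination import bootstrap_support, bray_curtis_matrix, nmds
from .enrichment import enrich
from .io_model import write_matrix
from .orthology import OrthologyParams, build_families, partition_families, summarize_partition
from .profiles import build_profiles, compare_clades
from .synthetic import SimulationConfig, generate, hypothetical_flags, write_dataset

logger = logging.getLogger("nichecomp.pipeline")

STAGES = ("simulate", "orthology", "profiles", "cluster", "cazy", "enrich")


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted-keys) JSON form of a config."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, name: str, status: str, outputs: list[Path], error: str | None = None):
        self.stages.append(
            {
                "name": name,
                "status": status,
                "outputs": [str(p) for p in outputs],
                **({"error": error} if error else {}),
            }
        )

    @property
    def ok(self) -> bool:
        return all(s["status"] == "success" for s in self.stages)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def run_all(config: dict, outdir: str | Path) -> RunManifest:
    """Run every stage on a simulated dataset; returns the manifest.

    ``config`` may carry a ``simulate`` block (SimulationConfig fields),
    an ``orthology`` block (OrthologyParams fields plus ``strict_core``),
    a ``cluster`` block (``n_boot``, ``n_starts``) and a ``seed``.
    A stage failure is recorded in the manifest and re-raised after the
    manifest is written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        version=__version__, config_hash=config_hash(config), seed=seed
    )
    try:
        # -- simulate ----------------------------------------------------
        sim_cfg = SimulationConfig(**{**config.get("simulate", {}), "seed": seed})
        dataset = generate(sim_cfg)
        paths = write_dataset(dataset, outdir / "data")
        manifest.record("simulate", "success", sorted(paths.values()))

        # -- orthology ---------------------------------------------------
        orth_block = dict(config.get("orthology", {}))
        strict_core = bool(orth_block.pop("strict_core", True))
        params = OrthologyParams(**orth_block)
        proteomes = dataset.proteomes
        families = build_families(list(proteomes.values()), params)
        partition = partition_families(
            families, proteomes, dataset.design, strict_core=strict_core, params=params
        )
        summary = summarize_partition(partition, families, hypothetical_flags(dataset))
        fam_path = outdir / "families.tsv"
        pd.DataFrame(
            [
                (f.family_id, g, p)
                for f in families
                for (g, p) in sorted(f.members)
            ],
            columns=["family_id", "genome_id", "protein_id"],
        ).to_csv(fam_path, sep="\t", index=False)
        part_path = outdir / "partition.tsv"
        pd.DataFrame(
            [
                (fid, role)
                for role in ("core", "niche_specific_A", "niche_specific_B", "accessory")
                for fid in sorted(getattr(partition, role))
            ],
            columns=["family_id", "set"],
        ).to_csv(part_path, sep="\t", index=False)
        sum_path = outdir / "summary.txt"
        with open(sum_path, "w") as fh:
            for name, entry in summary.items():
                line = f"{name}: {entry['size']} families, {entry['hypothetical']} hypothetical"
                if "percent" in entry:
                    line += f" ({entry['percent']}%)"
                fh.write(line + "\n")
        manifest.record("orthology", "success", [fam_path, part_path, sum_path])

        # -- profiles ----------------------------------------------------
        profiles = build_profiles(dataset.annotations, proteomes, level=1)
        comparison = compare_clades(profiles, dataset.design)
        prof_path = outdir / "profiles.tsv"
        write_matrix(profiles, prof_path)
        comp_path = outdir / "clade_comparison.tsv"
        comparison.to_csv(comp_path, sep="\t", index=False)
        manifest.record("profiles", "success", [prof_path, comp_path])

        # -- cluster + ordination ---------------------------------------
        cl_cfg = config.get("cluster", {})
        dm = bray_curtis_matrix(profiles)
        dist_path = outdir / "distance.tsv"
        write_matrix(dm.to_frame(), dist_path)
        tree = bootstrap_support(
            profiles, n_reps=int(cl_cfg.get("n_boot", 1000)), seed=seed
        )
        tree_path = outdir / "tree.nwk"
        tree_path.write_text(tree.to_newick() + "\n")
        ordination = nmds(
            dm, k=2, n_starts=int(cl_cfg.get("n_starts", 8)), seed=seed
        )
        coords_path = outdir / "nmds_coords.tsv"
        write_matrix(ordination.coordinates, coords_path)
        stress_path = outdir / "stress.txt"
        stress_path.write_text(f"{ordination.stress:.6f}\n")
        manifest.record(
            "cluster", "success", [dist_path, tree_path, coords_path, stress_path]
        )

        # -- enzyme accounting ------------------------------------------
        consensus = consensus_annotation(dataset.predictions, mode="family")
        matrix = family_matrix(consensus, genomes=list(proteomes))
        mat_path = outdir / "family_matrix.tsv"
        write_matrix(matrix.counts.astype(float), mat_path)
        uniq_rows = []
        for clade in dataset.design.clade_labels:
            for fam in sorted(clade_unique_families(matrix, dataset.design, clade)):
                uniq_rows.append((clade, fam))
        uniq_path = outdir / "unique_families.tsv"
        pd.DataFrame(uniq_rows, columns=["clade", "family"]).to_csv(
            uniq_path, sep="\t", index=False
        )
        shan_path = outdir / "shannon.tsv"
        pd.concat(
            [shannon_by_genome(matrix, "family"), shannon_by_genome(matrix, "class")],
            axis=1,
        ).to_csv(shan_path, sep="\t", index_label="genome_id")
        ratios = lifestyle_ratio(matrix, dataset.design)
        ratio_path = outdir / "ratios.tsv"
        ratios.per_genome.to_csv(ratio_path, sep="\t", index=False)
        clade_ratio_path = outdir / "ratios_by_clade.tsv"
        ratios.per_clade.to_csv(clade_ratio_path, sep="\t", index=False)
        manifest.record(
            "cazy", "success", [mat_path, uniq_path, shan_path, ratio_path, clade_ratio_path]
        )

        # -- enrichment --------------------------------------------------
        # categories of clade-A niche-specific proteins against the whole
        # annotated complement of the clade-A reference genomes
        fam_by_id = {f.family_id: f for f in families}
        spec_proteins = {
            (g, p)
            for fid in partition.niche_specific_A
            for (g, p) in fam_by_id[fid].members
        }
        ref_genomes = set(dataset.design.reference("A"))
        ann = dataset.annotations
        ref_ann = ann[ann["genome_id"].isin(ref_genomes)]
        ref_map = ref_ann.assign(
            key=ref_ann["genome_id"] + ":" + ref_ann["protein_id"]
        )[["key", "level1_category"]]
        set_keys = {f"{g}:{p}" for (g, p) in spec_proteins if g in ref_genomes}
        set_map = ref_map[ref_map["key"].isin(set_keys)]
        enr_path = outdir / "enrichment.tsv"
        if set_map.empty:
            pd.DataFrame().to_csv(enr_path, sep="\t")
        else:
            enrich(set_map, ref_map).to_csv(enr_path, sep="\t", index=False)
        manifest.record("enrich", "success", [enr_path])
    except Exception as exc:  # record the failing stage, then re-raise
        done = {s["name"] for s in manifest.stages}
        failed = next(s for s in STAGES if s not in done)
        manifest.record(failed, "failed", [], error=str(exc))
        manifest.finished = time.time()
        manifest.write(outdir / "manifest.json")
        raise
    manifest.finished = time.time()
    manifest.write(outdir / "manifest.json")
    logger.info("pipeline finished: %d stages", len(manifest.stages))
    return manifest
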