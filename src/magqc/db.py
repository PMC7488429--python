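"""The marker database as an on-disk directory and in-memory object.

Layout of a database directory::

    manifest.yaml      construction parameters, file inventory, content hash
    thresholds.tsv     profile_id -> noise-cutoff bit score
    sets.tsv           one row per (set_id, node_id, profile_id, prevalence)
    reference_set.tsv  placement reference profiles with exemplar genomes
    tree.nwk           rooted reference tree, leaves = genome ids
    lineages.tsv       genome_id -> rank:name;rank:name;...

Node ids are assigned deterministically from tree topology (preorder), so a
database re-saved after loading reproduces its files byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import InputError
from .hits import ProfileHit
from .reference_db import (
    DbConfig,
    MarkerCountMatrix,
    MarkerSet,
    ReferenceSetResult,
    best_reference_genomes,
    build_count_matrix,
    build_reference_set,
    calibrate_thresholds,
    define_clade_sets,
    select_balanced_subset,
)
from .tree import ReferenceTree, read_lineage_table, write_lineage_table

FORMAT_VERSION = 1


@dataclass
class MarkerDatabase:
    """Everything needed to score a query genome."""

    config: DbConfig
    thresholds: dict[str, float]
    tree: ReferenceTree
    sets: list[MarkerSet]
    reference_profiles: tuple[str, ...]
    reference_exemplars: dict[str, str]
    under_covered: tuple[str, ...] = ()

    def set_by_id(self, set_id: str) -> MarkerSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise InputError(f"unknown set {set_id!r}")

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        hits: Sequence[ProfileHit],
        tree: ReferenceTree,
        config: DbConfig | None = None,
        balance_table: pd.DataFrame | None = None,
    ) -> "MarkerDatabase":
        """Build the full database from a hit table and a reference tree.

        Pipeline order: bit-score thresholds (on a taxonomically balanced
        genome subset when ``balance_table`` provides clade/phylum labels,
        otherwise on all genomes) -> copy-count matrix -> greedy placement
        reference set -> clade-specific marker sets.
        """
        config = config or DbConfig()
        calibration_genomes = (
            select_balanced_subset(balance_table, config)
            if balance_table is not None
            else None
        )
        thresholds = calibrate_thresholds(hits, genomes=calibration_genomes)
        matrix = build_count_matrix(hits, thresholds)
        missing = set(tree.leaf_ids()) - set(matrix.genomes)
        if missing:
            raise InputError(
                f"tree leaves absent from the hit table: {sorted(missing)}"
            )
        reference = build_reference_set(matrix, config)
        exemplars = best_reference_genomes(hits, matrix, reference.profiles)
        sets = define_clade_sets(tree, matrix, config)
        return cls(
            config=config,
            thresholds=thresholds,
            tree=tree,
            sets=sets,
            reference_profiles=reference.profiles,
            reference_exemplars=exemplars,
            under_covered=reference.under_covered,
        )

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        thr = pd.DataFrame(
            sorted(self.thresholds.items()), columns=["profile_id", "threshold"]
        )
        thr.to_csv(directory / "thresholds.tsv", sep="\t", index=False)

        rows = [
            (s.set_id, s.node_id, p, s.prevalence.get(p, 1.0))
            for s in sorted(self.sets, key=lambda s: s.set_id)
            for p in s.profile_ids
        ]
        pd.DataFrame(
            rows, columns=["set_id", "node_id", "profile_id", "prevalence"]
        ).to_csv(directory / "sets.tsv", sep="\t", index=False)

        ref = pd.DataFrame(
            [
                (p, self.reference_exemplars.get(p, ""))
                for p in self.reference_profiles
            ],
            columns=["profile_id", "exemplar_genome"],
        )
        ref.to_csv(directory / "reference_set.tsv", sep="\t", index=False)

        (directory / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        write_lineage_table(self.tree.lineages, directory / "lineages.tsv")

        manifest = {
            "format_version": FORMAT_VERSION,
            "config": {
                "prevalence_cutoff": self.config.prevalence_cutoff,
                "min_species": self.config.min_species,
                "min_profiles": self.config.min_profiles,
                "min_cover": self.config.min_cover,
                "max_per_clade": self.config.max_per_clade,
                "seed": self.config.seed,
            },
            "n_sets": len(self.sets),
            "n_reference_profiles": len(self.reference_profiles),
            "under_covered_genomes": list(self.under_covered),
            "files": {},
        }
        for name in ("thresholds.tsv", "sets.tsv", "reference_set.tsv",
                     "tree.nwk", "lineages.tsv"):
            digest = hashlib.sha256((directory / name).read_bytes()).hexdigest()
            manifest["files"][name] = digest
        with open(directory / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "MarkerDatabase":
        directory = Path(directory)
        manifest_path = directory / "manifest.yaml"
        if not manifest_path.exists():
            raise InputError(f"{directory} is not a marker database (no manifest)")
        manifest = yaml.safe_load(manifest_path.read_text())
        if manifest.get("format_version") != FORMAT_VERSION:
            raise InputError("unsupported database format version")
        config = DbConfig(**manifest["config"])

        lineages = read_lineage_table(directory / "lineages.tsv")
        tree = ReferenceTree.from_file(directory / "tree.nwk", lineages)

        thr_frame = pd.read_csv(directory / "thresholds.tsv", sep="\t")
        thresholds = {
            str(r.profile_id): float(r.threshold)
            for r in thr_frame.itertuples(index=False)
        }

        sets_frame = pd.read_csv(directory / "sets.tsv", sep="\t")
        sets: list[MarkerSet] = []
        if len(sets_frame) > 0:
            for (set_id, node_id), grp in sets_frame.groupby(
                ["set_id", "node_id"], sort=True
            ):
                sets.append(
                    MarkerSet(
                        set_id=str(set_id),
                        node_id=str(node_id),
                        profile_ids=tuple(sorted(map(str, grp["profile_id"]))),
                        species_ids=tuple(sorted(tree.leaves_below[str(node_id)])),
                        prevalence={
                            str(r.profile_id): float(r.prevalence)
                            for r in grp.itertuples(index=False)
                        },
                    )
                )

        ref_frame = pd.read_csv(
            directory / "reference_set.tsv", sep="\t", keep_default_na=False
        )
        reference_profiles = tuple(str(p) for p in ref_frame["profile_id"])
        exemplars = {
            str(r.profile_id): str(r.exemplar_genome)
            for r in ref_frame.itertuples(index=False)
            if str(r.exemplar_genome)
        }
        return cls(
            config=config,
            thresholds=thresholds,
            tree=tree,
            sets=sets,
            reference_profiles=reference_profiles,
            reference_exemplars=exemplars,
            under_covered=tuple(manifest.get("under_covered_genomes", [])),
        )

    def manifest_hash(self) -> str:
        """Content hash over the canonical database tables (provenance)."""
        h = hashlib.sha256()
        for profile in sorted(self.thresholds):
            h.update(f"{profile}={self.thresholds[profile]}".encode())
        for s in sorted(self.sets, key=lambda s: s.set_id):
            h.update(f"{s.set_id}:{s.node_id}:{','.join(s.profile_ids)}".encode())
        h.update(",".join(self.reference_profiles).encode())
        return h.hexdigest()[:16]
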