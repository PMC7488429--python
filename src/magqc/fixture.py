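"""Fully synthetic reference corpora for building and testing databases.

Real marker databases are mined from hundreds of annotated reference
proteomes; this module synthesises a self-consistent miniature corpus — a
random rooted species tree, per-profile bit-score thresholds, a marker
copy-count matrix, a hit table and proteomes consistent with that matrix,
genome coordinates with marker loci, and tree-derived lineages — so the
entire pipeline can be exercised end to end with exact ground truth.

The copy-count model is deliberately simple: each (genome, profile) cell is
single-copy with probability ``1 - dropout``, absent with probability
``dropout * (1 - duplication_rate)`` and duplicated otherwise.  It captures
the feature the method relies on (high single-copy prevalence within
clades) but none of the phylogenetic correlation of real marker loss, so a
fixture validates the machinery, not the biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .hits import ProfileHit
from .reference_db import MarkerCountMatrix
from .simulate import Fragment, SimulatedGenome, markers_on_fragments
from .tree import Lineage, ReferenceTree

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
DNA_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class AnnotatedQuery:
    """Exact annotation of a simulated genome (oracle in place of HMM scans)."""

    hits: tuple[ProfileHit, ...]
    protein_contigs: Mapping[str, str]
    contig_lengths: Mapping[str, int]


@dataclass
class ReferenceFixture:
    tree: ReferenceTree
    matrix: MarkerCountMatrix
    thresholds: dict[str, float]
    hits: list[ProfileHit]
    proteomes: dict[str, list[tuple[str, str]]]
    genome_lengths: dict[str, dict[str, int]]
    marker_maps: dict[str, list[tuple[str, int, str]]]
    lineages: dict[str, Lineage]
    seed: int

    @property
    def species(self) -> list[str]:
        return self.tree.leaf_ids()

    @property
    def profiles(self) -> list[str]:
        return self.matrix.profiles

    def genome_sequences(self, species: str) -> dict[str, str]:
        """Deterministic synthetic chromosome sequences for one species."""
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, _stable_index(self.species, species)])
        )
        return {
            contig: "".join(rng.choice(DNA_ALPHABET, size=length))
            for contig, length in self.genome_lengths[species].items()
        }

    def annotate(self, sim: SimulatedGenome, query_id: str = "query") -> AnnotatedQuery:
        """Exact marker annotation of a simulated genome.

        Each marker locus landing on a kept fragment yields one hit, scored
        above any threshold calibratable from this corpus (reference scores
        top out 50 bits above the generating threshold); the fragment
        becomes the protein's contig.  This plays the role of gene prediction plus HMM
        scanning with zero annotation error, which is exactly what a
        parameter-recovery benchmark needs.
        """
        hits: list[ProfileHit] = []
        protein_contigs: dict[str, str] = {}
        serial: dict[str, int] = {}
        for frag in sim.fragments:
            frag_counts = markers_on_fragments([frag], self.marker_maps)
            for profile, copies in sorted(frag_counts.items()):
                for _ in range(copies):
                    k = serial.get(profile, 0)
                    serial[profile] = k + 1
                    protein = f"{query_id}_{profile}_{k}"
                    hits.append(
                        ProfileHit(query_id, protein, profile, self.thresholds[profile] + 60.0)
                    )
                    protein_contigs[protein] = frag.fragment_id
        contig_lengths = {f.fragment_id: f.length for f in sim.fragments}
        return AnnotatedQuery(tuple(hits), protein_contigs, contig_lengths)


def _stable_index(items: Sequence[str], item: str) -> int:
    return sorted(items).index(item)


def _random_topology(
    labels: list[str], rng: np.random.Generator, max_depth: int
) -> str:
    if len(labels) == 1:
        return labels[0]
    if max_depth <= 0:
        return "(" + ",".join(labels) + ")"
    cut = int(rng.integers(1, len(labels)))
    left = _random_topology(labels[:cut], rng, max_depth - 1)
    right = _random_topology(labels[cut:], rng, max_depth - 1)
    return f"({left},{right})"


def synthesize_reference_fixture(
    n_species: int = 16,
    tree_depth: int = 4,
    n_profiles: int = 100,
    per_profile_dropout: float = 0.02,
    duplication_rate: float = 0.1,
    seed: int = 0,
    genome_length: int = 5_000_000,
    n_contigs: int = 4,
    noise_hit_rate: float = 0.1,
    protein_length: int = 120,
) -> ReferenceFixture:
    """Generate a synthetic reference corpus.

    Defaults give sixteen 5-Mb species genomes carrying 100 marker
    profiles, 2% marker dropout and a 10% duplication rate among dropped
    cells — a miniature of a curated reference proteome collection, small
    enough to rebuild in milliseconds.  ``noise_hit_rate`` adds
    sub-threshold decoy hits so thresholding actually has work to do.
    Deterministic given ``seed``.
    """
    if n_species < 4:
        raise InputError("n_species must be >= 4")
    if n_profiles < 1:
        raise InputError("n_profiles must be >= 1")
    if not 0 <= per_profile_dropout < 1 or not 0 <= duplication_rate <= 1:
        raise InputError("rates must lie in [0, 1)")
    if tree_depth < 2:
        raise InputError("tree_depth must be >= 2")
    rng = np.random.default_rng(seed)

    width = max(3, len(str(n_species - 1)))
    species = [f"sp{str(i).zfill(width)}" for i in range(n_species)]
    profiles = [f"PF{str(i).zfill(4)}" for i in range(n_profiles)]

    newick = _random_topology(list(species), rng, tree_depth) + ";"
    tree = ReferenceTree.from_newick(newick)

    lineages: dict[str, Lineage] = {}
    for leaf in tree.leaf_ids():
        chain = list(reversed(tree.ancestors(leaf)))  # root ... parent
        lineage = [("domain", "Eukaryota")]
        for level, node_id in enumerate(chain[1:], start=1):
            lineage.append((f"rank{level}", f"taxon_{node_id}"))
        lineage.append(("species", leaf))
        lineages[leaf] = tuple(lineage)
    tree.lineages = lineages

    # copy-count model
    u = rng.random((n_species, n_profiles))
    dup = rng.random((n_species, n_profiles)) < duplication_rate
    counts = np.where(u < 1 - per_profile_dropout, 1, np.where(dup, 2, 0))

    import pandas as pd

    frame = pd.DataFrame(counts, index=species, columns=profiles)
    frame.index.name = "genome_id"
    frame.columns.name = "profile_id"
    matrix = MarkerCountMatrix(frame)

    thresholds = {
        p: round(float(rng.uniform(50, 150)), 1) for p in profiles
    }

    hits: list[ProfileHit] = []
    proteomes: dict[str, list[tuple[str, str]]] = {g: [] for g in species}
    for gi, genome in enumerate(species):
        for pi, profile in enumerate(profiles):
            for k in range(int(counts[gi, pi])):
                protein = f"{genome}_{profile}_{k}"
                score = round(thresholds[profile] + float(rng.uniform(1, 50)), 1)
                hits.append(ProfileHit(genome, protein, profile, score))
                seq = "".join(rng.choice(AA_ALPHABET, size=protein_length))
                proteomes[genome].append((protein, seq))
            if rng.random() < noise_hit_rate:
                decoy = f"{genome}_{profile}_decoy"
                score = round(thresholds[profile] - float(rng.uniform(1, 20)), 1)
                hits.append(ProfileHit(genome, decoy, profile, score))
        if not any(h.genome_id == genome for h in hits):
            # keep every genome visible in the hit table
            hits.append(ProfileHit(genome, f"{genome}_empty", profiles[0],
                                   thresholds[profiles[0]] - 5.0))

    # genomes and marker loci
    genome_lengths: dict[str, dict[str, int]] = {}
    marker_maps: dict[str, list[tuple[str, int, str]]] = {}
    contig_len = genome_length // n_contigs
    for gi, genome in enumerate(species):
        contigs = {f"chr{c + 1}": contig_len for c in range(n_contigs)}
        genome_lengths[genome] = contigs
        loci: list[tuple[str, int, str]] = []
        for pi, profile in enumerate(profiles):
            for _ in range(int(counts[gi, pi])):
                contig = f"chr{int(rng.integers(1, n_contigs + 1))}"
                pos = int(rng.integers(0, contig_len))
                loci.append((contig, pos, profile))
        marker_maps[genome] = loci

    return ReferenceFixture(
        tree=tree,
        matrix=matrix,
        thresholds=thresholds,
        hits=hits,
        proteomes=proteomes,
        genome_lengths=genome_lengths,
        marker_maps=marker_maps,
        lineages=lineages,
        seed=seed,
    )
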