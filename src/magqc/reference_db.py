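"""Marker-gene database construction.

The database is mined from three inputs: a table of profile-HMM hits against
annotated reference proteomes, a rooted reference tree over the same
genomes, and per-genome taxonomic lineages.  Construction proceeds in four
steps:

1. **Bit-score threshold calibration** — for each profile, choose the noise
   cutoff that maximises the number of reference genomes carrying *exactly
   one* above-threshold hit.  A stringent per-profile cutoff separates
   orthologs from paralogs and spurious domain-level matches.
2. **Copy-count matrix** — apply the thresholds and count, per genome and
   profile, the number of distinct proteins matched.
3. **Greedy reference set** — a small, overlapping collection of profiles
   that jointly covers every reference genome as a single-copy marker at
   least ``min_cover`` times; used for the initial phylogenetic placement of
   query proteins.
4. **Clade-specific marker sets** — for every tree clade of at least
   ``min_species`` genomes, the profiles whose single-copy prevalence in the
   clade reaches ``prevalence_cutoff``; a set is emitted when at least
   ``min_profiles`` qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .hits import ProfileHit, hits_to_frame

__all__ = [
    "DbConfig",
    "MarkerCountMatrix",
    "MarkerSet",
    "ReferenceSetResult",
    "select_balanced_subset",
    "calibrate_threshold",
    "calibrate_thresholds",
    "build_count_matrix",
    "single_copy_prevalence",
    "define_clade_sets",
    "build_reference_set",
]


@dataclass(frozen=True)
class DbConfig:
    """Tunable constants of database construction.

    prevalence_cutoff:
        Minimum single-copy prevalence (fraction of clade genomes with
        exactly one copy) for a profile to enter a clade set.
    min_species:
        Smallest clade (leaf count) eligible for a marker set.
    min_profiles:
        Smallest number of qualifying profiles that justifies a set.
    min_cover:
        Target per-genome coverage of the greedy placement reference set.
    max_per_clade:
        Genome cap per major clade in taxonomically balanced subsetting.
    """

    prevalence_cutoff: float = 0.98
    min_species: int = 3
    min_profiles: int = 20
    min_cover: int = 3
    max_per_clade: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_cutoff <= 1:
            raise InputError("prevalence_cutoff must be in (0, 1]")
        if self.min_species < 2:
            raise InputError("min_species must be >= 2")
        if self.min_profiles < 1:
            raise InputError("min_profiles must be >= 1")
        if self.min_cover < 1:
            raise InputError("min_cover must be >= 1")
        if self.max_per_clade < 1:
            raise InputError("max_per_clade must be >= 1")


class MarkerCountMatrix:
    """Genomes x profiles matrix of above-threshold marker copy counts."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if (frame.values < 0).any():
            raise InputError("copy counts must be non-negative")
        self.df = frame.astype(int)

    @property
    def genomes(self) -> list[str]:
        return list(self.df.index)

    @property
    def profiles(self) -> list[str]:
        return list(self.df.columns)

    def count(self, genome_id: str, profile_id: str) -> int:
        return int(self.df.at[genome_id, profile_id])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerCountMatrix) and self.df.equals(other.df)


@dataclass(frozen=True)
class MarkerSet:
    """A clade-specific set of single-copy marker profiles.

    ``prevalence`` maps each member profile to its single-copy prevalence
    over ``species_ids`` (the genomes of the defining clade).
    """

    set_id: str
    node_id: str
    profile_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    prevalence: Mapping[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.profile_ids)


@dataclass(frozen=True)
class ReferenceSetResult:
    """Greedy placement reference set, with any genomes left under-covered."""

    profiles: tuple[str, ...]
    under_covered: tuple[str, ...]

    @property
    def feasible(self) -> bool:
        return not self.under_covered


def select_balanced_subset(table: pd.DataFrame, config: DbConfig) -> list[str]:
    """Taxonomically balanced genome subset for threshold calibration.

    ``table`` needs columns ``genome_id``, ``clade`` (major clade, e.g.
    Opisthokonta) and ``phylum``.  Per clade at most ``max_per_clade``
    genomes are kept, drawn round-robin across the clade's phyla so that
    selected counts per phylum differ by at most one among phyla that still
    have genomes left.  Deterministic given ``config.seed``.
    """
    required = {"genome_id", "clade", "phylum"}
    if missing := required - set(table.columns):
        raise InputError(f"balance table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise InputError("no genomes")
    rng = np.random.default_rng(config.seed)
    selected: list[str] = []
    for clade in sorted(table["clade"].unique()):
        sub = table[table["clade"] == clade]
        if len(sub) <= config.max_per_clade:
            selected.extend(sorted(sub["genome_id"]))
            continue
        queues = {}
        for phylum in sorted(sub["phylum"].unique()):
            genomes = sorted(sub.loc[sub["phylum"] == phylum, "genome_id"])
            rng.shuffle(genomes)
            queues[phylum] = genomes
        order = sorted(queues)
        rng.shuffle(order)
        taken = 0
        while taken < config.max_per_clade:
            progressed = False
            for phylum in order:
                if taken >= config.max_per_clade:
                    break
                if queues[phylum]:
                    selected.append(queues[phylum].pop())
                    taken += 1
                    progressed = True
            if not progressed:
                break
    return selected


def calibrate_threshold(scores_by_genome: Mapping[str, Sequence[float]]) -> float:
    """Noise-cutoff bit score for one profile.

    Scans the candidate grid of distinct observed bit scores and returns the
    threshold ``t`` maximising the number of genomes with exactly one hit
    scoring ``>= t``; ties are broken toward the largest ``t`` (the most
    stringent cutoff, favouring paralog separation).  Values between two
    observed scores are equivalent to the upper one, so the observed grid is
    exhaustive.
    """
    pairs = [
        (np.max(s), np.partition(s, -2)[-2] if len(s) > 1 else -np.inf)
        for s in (np.asarray(list(v), dtype=float) for v in scores_by_genome.values())
        if len(s) > 0
    ]
    if not pairs:
        raise InputError("no hits for profile")
    best = np.array([p[0] for p in pairs])
    second = np.array([p[1] for p in pairs])
    grid = np.unique(best)  # thresholds above every best score win nothing
    grid = np.union1d(grid, np.unique(second[np.isfinite(second)]))
    # exactly one hit >= t  <=>  second_best < t <= best
    counts = (best[None, :] >= grid[:, None]).sum(axis=1) - (
        second[None, :] >= grid[:, None]
    ).sum(axis=1)
    top = counts.max()
    return float(grid[np.nonzero(counts == top)[0][-1]])


def calibrate_thresholds(
    hits: Iterable[ProfileHit],
    genomes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-profile thresholds from a hit table.

    If ``genomes`` is given (e.g. a taxonomically balanced subset),
    calibration only counts hits from those genomes.
    """
    frame = hits_to_frame(hits)
    if genomes is not None:
        frame = frame[frame["genome_id"].isin(set(genomes))]
    thresholds: dict[str, float] = {}
    for profile, grp in frame.groupby("profile_id", sort=True):
        by_genome = {
            g: sub["bit_score"].to_numpy() for g, sub in grp.groupby("genome_id")
        }
        thresholds[str(profile)] = calibrate_threshold(by_genome)
    return thresholds


def build_count_matrix(
    hits: Iterable[ProfileHit],
    thresholds: Mapping[str, float],
) -> MarkerCountMatrix:
    """Count distinct above-threshold proteins per (genome, profile).

    The threshold comparison is inclusive (``bit_score >= threshold``), and
    a protein contributes at most once per profile regardless of how many
    domain-level matches it produced.  Rows cover every genome seen in the
    hit table (even if all its hits fall below threshold); columns cover
    every profile in ``thresholds``; both are sorted.
    """
    frame = hits_to_frame(hits)
    profiles = sorted(thresholds)
    unknown = set(frame["profile_id"]) - set(profiles)
    if unknown:
        raise InputError(f"hit references profile(s) without threshold: {sorted(unknown)}")
    genomes = sorted(frame["genome_id"].unique())
    if len(frame) > 0:
        cutoff = frame["profile_id"].map(thresholds)
        frame = frame[frame["bit_score"] >= cutoff]
        frame = frame.drop_duplicates(subset=["genome_id", "profile_id", "protein_id"])
    if len(frame) == 0:
        counts = pd.DataFrame(0, index=genomes, columns=profiles, dtype=int)
    else:
        counts = (
            frame.groupby(["genome_id", "profile_id"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(index=genomes, columns=profiles, fill_value=0)
        )
    counts.index.name = "genome_id"
    counts.columns.name = "profile_id"
    return MarkerCountMatrix(counts)


def single_copy_prevalence(
    matrix: MarkerCountMatrix,
    clade_genomes: Sequence[str],
    profile_id: str,
) -> float:
    """Fraction of clade genomes carrying exactly one copy of the profile."""
    if len(clade_genomes) == 0:
        raise InputError("empty clade")
    unknown = set(clade_genomes) - set(matrix.genomes)
    if unknown:
        raise InputError(f"unknown genome(s): {sorted(unknown)}")
    if profile_id not in matrix.df.columns:
        raise InputError(f"unknown profile {profile_id!r}")
    col = matrix.df.loc[list(clade_genomes), profile_id]
    return float((col == 1).mean())


def define_clade_sets(
    tree,
    matrix: MarkerCountMatrix,
    config: DbConfig,
) -> list[MarkerSet]:
    """Mine a marker set for every eligible clade of the reference tree.

    Every internal node whose clade holds at least ``min_species`` leaves is
    examined; profiles whose single-copy prevalence in the clade reaches
    ``prevalence_cutoff`` qualify, and a :class:`MarkerSet` is emitted iff at
    least ``min_profiles`` qualify.  Set ids derive deterministically from
    node ids.
    """
    missing = set(tree.leaf_ids()) - set(matrix.genomes)
    if missing:
        raise InputError(f"tree leaves missing from matrix: {sorted(missing)}")
    sets: list[MarkerSet] = []
    for node_id in tree.internal_ids():
        clade = sorted(tree.leaves_below[node_id])
        if len(clade) < config.min_species:
            continue
        sub = matrix.df.loc[clade]
        prevalence = (sub == 1).mean(axis=0)
        qualifying = prevalence[prevalence >= config.prevalence_cutoff]
        if len(qualifying) < config.min_profiles:
            continue
        sets.append(
            MarkerSet(
                set_id=f"set_{node_id}",
                node_id=node_id,
                profile_ids=tuple(sorted(qualifying.index)),
                species_ids=tuple(clade),
                prevalence={p: float(qualifying[p]) for p in sorted(qualifying.index)},
            )
        )
    return sets


def build_reference_set(matrix: MarkerCountMatrix, config: DbConfig) -> ReferenceSetResult:
    """Greedy overlapping cover of all genomes by single-copy profiles.

    Repeatedly selects the profile that is single-copy in the largest number
    of genomes still below ``min_cover`` coverage (ties broken toward the
    lexicographically smallest profile id) until every genome is covered
    ``min_cover`` times or no profile adds coverage.  When some genome
    cannot reach ``min_cover``, the best-effort set is returned together
    with the under-covered genomes.
    """
    if len(matrix.genomes) == 0 or len(matrix.profiles) == 0:
        raise InputError("empty count matrix")
    single = (matrix.df.values == 1)  # genomes x profiles
    n_genomes = single.shape[0]
    coverage = np.zeros(n_genomes, dtype=int)
    available = np.ones(single.shape[1], dtype=bool)
    chosen: list[str] = []
    while True:
        needy = coverage < config.min_cover
        if not needy.any():
            break
        gains = np.where(available, single[needy].sum(axis=0), -1)
        best = int(gains.argmax())  # first max = lexicographically smallest column
        if gains[best] <= 0:
            break
        available[best] = False
        chosen.append(matrix.profiles[best])
        coverage += single[:, best]
    under = tuple(
        g for g, c in zip(matrix.genomes, coverage) if c < config.min_cover
    )
    return ReferenceSetResult(profiles=tuple(chosen), under_covered=under)


def best_reference_genomes(
    hits: Iterable[ProfileHit],
    matrix: MarkerCountMatrix,
    reference_profiles: Sequence[str],
) -> dict[str, str]:
    """For each reference-set profile, the single-copy genome with the
    strongest hit (ties toward the lexicographically smallest genome id).

    This per-profile exemplar anchors the built-in fallback placement.
    """
    frame = hits_to_frame(hits)
    out: dict[str, str] = {}
    for profile in reference_profiles:
        singles = {g for g in matrix.genomes if matrix.count(g, profile) == 1}
        sub = frame[(frame["profile_id"] == profile) & frame["genome_id"].isin(singles)]
        if len(sub) == 0:
            continue
        sub = sub.sort_values(["bit_score", "genome_id"], ascending=[False, True])
        out[profile] = str(sub.iloc[0]["genome_id"])
    return out
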