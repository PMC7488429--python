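"""Benchmark genome simulation: fragmentation, incompleteness, contamination.

The simulator reproduces the benchmark design used to evaluate marker-based
quality estimates: a complete reference genome is cut into contig-sized
fragments by stepping along each chromosome with Poisson-distributed step
sizes (floored at ``min_step``), fragments are kept independently at a
target probability to simulate incompleteness, and contaminating fragments
— produced the same way from a second genome of the same clade, a different
clade, or i.i.d. random DNA — are appended.  Every fragment carries its
source coordinates and a target/contaminant label, so the expected
completeness and contamination of each simulated genome are known exactly.

Fragmentation and subsampling operate on coordinates only; bases are
materialised only when a FASTA file is written, so large benchmark genomes
cost almost nothing to simulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError

TARGET = "target"
CONTAMINANT = "contaminant"
RANDOM_DNA_SOURCE = "random_dna"
CONTAMINANT_MODES = ("same_clade", "out_clade", "random_dna")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Fragment lengths are ``max(min_step, step_unit * Poisson(poisson_lambda))``
    base pairs.  With the defaults (lambda 100, unit 100 bp, floor 2000 bp)
    fragments span roughly 2-20 kb, i.e. metagenome-assembly contig sizes;
    ``step_unit=1`` recovers a literal base-pair reading of the Poisson draw,
    in which the 2000-bp floor dominates.

    ``contamination_fraction`` is the kept fraction of the *contaminant*
    genome's length — the same size-fraction logic used for the target.
    """

    poisson_lambda: float = 100.0
    step_unit: int = 100
    min_step: int = 2000
    target_fraction: float = 1.0
    contamination_fraction: float = 0.0
    contaminant_mode: str = "same_clade"
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_step < 1 or self.step_unit < 1:
            raise InputError("min_step and step_unit must be >= 1")
        if self.poisson_lambda <= 0:
            raise InputError("poisson_lambda must be positive")
        if not 0 < self.target_fraction <= 1:
            raise InputError("target_fraction must be in (0, 1]")
        if not 0 <= self.contamination_fraction < 1:
            raise InputError("contamination_fraction must be in [0, 1)")
        if self.contaminant_mode not in CONTAMINANT_MODES:
            raise InputError(f"unknown contaminant_mode {self.contaminant_mode!r}")
        if not 0 < self.gc_content < 1:
            raise InputError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class Fragment:
    """A contig of the simulated genome: a slice of a source chromosome.

    Coordinates are 0-based, half-open in the source sequence.
    """

    source: str
    contig: str
    start: int
    end: int
    label: str = TARGET

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fragment_id(self) -> str:
        return f"{self.source}|{self.contig}:{self.start}-{self.end}|{self.label}"


@dataclass(frozen=True)
class SimTruth:
    """Exact bookkeeping of what the simulated genome contains."""

    target_bp_total: int
    target_bp_kept: int
    contaminant_bp_total: int = 0
    contaminant_bp_kept: int = 0

    @property
    def realized_target_fraction(self) -> float:
        return self.target_bp_kept / self.target_bp_total

    @property
    def realized_contamination_fraction(self) -> float:
        if self.contaminant_bp_total == 0:
            return 0.0
        return self.contaminant_bp_kept / self.contaminant_bp_total


@dataclass(frozen=True)
class SimulatedGenome:
    fragments: tuple[Fragment, ...]
    truth: SimTruth
    config: SimConfig

    def fragments_with_label(self, label: str) -> list[Fragment]:
        return [f for f in self.fragments if f.label == label]


def _contig_lengths(sequences: Mapping[str, str | int]) -> dict[str, int]:
    out = {}
    for name, value in sequences.items():
        out[name] = value if isinstance(value, int) else len(value)
    return out


def fragment_genome(
    sequences: Mapping[str, str | int],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    source: str = "genome",
    label: str = TARGET,
) -> list[Fragment]:
    """Partition each chromosome left-to-right into Poisson-sized fragments.

    ``sequences`` maps chromosome name to sequence or to length.  Per
    chromosome the fragments tile ``[0, L)`` exactly; all fragments except
    possibly the terminal one are at least ``min_step`` long.  Deterministic
    given the generator state (or ``config.seed`` when ``rng`` is omitted).
    """
    if not sequences:
        raise InputError("no sequences to fragment")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fragments: list[Fragment] = []
    for contig in sorted(sequences):
        length = _contig_lengths(sequences)[contig]
        pos = 0
        while pos < length:
            step = max(config.min_step, int(rng.poisson(config.poisson_lambda)) * config.step_unit)
            end = min(pos + step, length)
            fragments.append(Fragment(source, contig, pos, end, label))
            pos = end
    return fragments


def subsample_to_fraction(
    fragments: Sequence[Fragment],
    target_fraction: float,
    rng: np.random.Generator | int,
) -> list[Fragment]:
    """Keep each fragment independently with probability ``target_fraction``."""
    if not 0 <= target_fraction <= 1:
        raise InputError("target_fraction must be in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    draws = rng.random(len(fragments))
    return [f for f, u in zip(fragments, draws) if u < target_fraction]


def make_contaminated_genome(
    target_genome: Mapping[str, str | int],
    contaminant_source: Mapping[str, str | int] | None,
    config: SimConfig,
    target_name: str = TARGET,
    contaminant_name: str = CONTAMINANT,
) -> SimulatedGenome:
    """Build a fragmented, incomplete, contaminated benchmark genome.

    The target is fragmented and subsampled to ``target_fraction`` of its
    length; the contaminant (a clade genome, or random DNA matching the
    target's total length in ``random_dna`` mode) is fragmented identically
    and subsampled to ``contamination_fraction`` of *its* length, then
    appended.  The truth record stores realized base-pair fractions.
    """
    rng = np.random.default_rng(config.seed)
    target_lengths = _contig_lengths(target_genome)
    target_total = sum(target_lengths.values())
    target_frags = fragment_genome(target_genome, config, rng, source=target_name)
    kept = subsample_to_fraction(target_frags, config.target_fraction, rng)

    contaminant_total = 0
    kept_contaminant: list[Fragment] = []
    if config.contamination_fraction > 0:
        if config.contaminant_mode == "random_dna":
            contaminant_source = {"chr1": target_total}
            contaminant_name = RANDOM_DNA_SOURCE
        elif contaminant_source is None:
            raise InputError(
                f"{config.contaminant_mode} contamination requires a contaminant genome"
            )
        contaminant_lengths = _contig_lengths(contaminant_source)
        contaminant_total = sum(contaminant_lengths.values())
        contaminant_frags = fragment_genome(
            contaminant_source, config, rng, source=contaminant_name, label=CONTAMINANT
        )
        kept_contaminant = subsample_to_fraction(
            contaminant_frags, config.contamination_fraction, rng
        )

    truth = SimTruth(
        target_bp_total=target_total,
        target_bp_kept=sum(f.length for f in kept),
        contaminant_bp_total=contaminant_total,
        contaminant_bp_kept=sum(f.length for f in kept_contaminant),
    )
    return SimulatedGenome(
        fragments=tuple(kept) + tuple(kept_contaminant), truth=truth, config=config
    )


def random_dna(length: int, gc_content: float, rng: np.random.Generator) -> str:
    """i.i.d. DNA with the given expected GC content."""
    probs = [
        (1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2,
    ]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=probs))


def materialize_fragments(
    sim: SimulatedGenome,
    sources: Mapping[str, Mapping[str, str]],
) -> list[tuple[str, str]]:
    """(fragment_id, sequence) pairs for a simulated genome.

    ``sources`` maps source name to its chromosome sequences.  Random-DNA
    fragments are synthesised deterministically from the simulation seed at
    the configured GC content.
    """
    rng = np.random.default_rng(sim.config.seed + 1)
    records = []
    for frag in sim.fragments:
        if frag.source == RANDOM_DNA_SOURCE:
            seq = random_dna(frag.length, sim.config.gc_content, rng)
        else:
            chromosomes = sources.get(frag.source)
            if chromosomes is None or frag.contig not in chromosomes:
                raise InputError(f"no sequence for fragment source {frag.source}/{frag.contig}")
            seq = chromosomes[frag.contig][frag.start : frag.end]
        records.append((frag.fragment_id, seq))
    return records


def write_simulated_fasta(
    sim: SimulatedGenome,
    sources: Mapping[str, Mapping[str, str]],
    path: str | Path,
) -> None:
    """FASTA of the simulated genome; headers encode source, coordinates, label."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=frag_id, description="")
        for frag_id, seq in materialize_fragments(sim, sources)
    ]
    seqio_write(records, str(path), "fasta")


def write_truth_table(sim: SimulatedGenome, path: str | Path) -> None:
    import pandas as pd

    rows = [
        (f.fragment_id, f.source, f.contig, f.start, f.end, f.label)
        for f in sim.fragments
    ]
    frame = pd.DataFrame(
        rows, columns=["fragment_id", "source_genome", "contig", "start", "end", "label"]
    )
    frame.to_csv(path, sep="\t", index=False)


def markers_on_fragments(
    fragments: Iterable[Fragment],
    marker_maps: Mapping[str, Sequence[tuple[str, int, str]]],
) -> dict[str, int]:
    """Copy count per profile recovered on a set of fragments.

    ``marker_maps`` maps source genome name to ``(contig, position,
    profile_id)`` marker loci; a locus is recovered by a fragment that
    contains its position.
    """
    counts: dict[str, int] = {}
    for frag in fragments:
        for contig, pos, profile in marker_maps.get(frag.source, ()):
            if contig == frag.contig and frag.start <= pos < frag.end:
                counts[profile] = counts.get(profile, 0) + 1
    return counts
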