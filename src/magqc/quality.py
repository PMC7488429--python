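"""Genome quality scoring against a chosen single-copy marker set.

Completeness is the percentage of the set's profiles found at least once in
the query; contamination is the percentage found in two or more copies.  A
duplicated profile is by construction also a found profile, so contamination
can never exceed completeness.  Each duplicated profile counts once toward
contamination regardless of its copy number (fraction-of-profiles
semantics); raw copy counts are kept on the report for inspection.

Two diagnostics accompany the scores: the fraction of genome length on
contigs that carry no marker hit (invisible to marker-based scoring), and a
marker-uniformity statistic — the Pearson correlation between cumulative
randomly sampled 5-kb genome fragments and the number of distinct markers
recovered, which approaches 1 when markers are spread uniformly along the
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .reference_db import MarkerSet
from .tree import Lineage


@dataclass(frozen=True)
class QualityReport:
    """Quality estimate for one query genome."""

    completeness: float
    contamination: float
    set_id: str
    n_profiles_in_set: int
    coverage_fraction: float
    lineage: Lineage
    unassessed_fraction: float | None = None
    profile_counts: Mapping[str, int] = field(default_factory=dict)
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100 or not 0 <= self.contamination <= 100:
            raise InputError("percentages out of range")
        if self.contamination > self.completeness + 1e-9:
            raise InputError("contamination cannot exceed completeness")


def estimate_quality(
    query_counts: Mapping[str, int],
    chosen_set: MarkerSet,
) -> tuple[float, float]:
    """(completeness %, contamination %) of a query against a marker set.

    ``query_counts`` maps profile ids to copy counts; profiles outside the
    set are ignored (with a warning suppressed here — callers that care
    filter beforehand), missing profiles count as absent.
    """
    if len(chosen_set) == 0:
        raise InputError("empty marker set")
    profiles = chosen_set.profile_ids
    found = sum(1 for p in profiles if query_counts.get(p, 0) >= 1)
    duplicated = sum(1 for p in profiles if query_counts.get(p, 0) >= 2)
    return 100.0 * found / len(profiles), 100.0 * duplicated / len(profiles)


def unassessed_fraction(
    contig_lengths: Mapping[str, int],
    marker_hit_contigs: set[str] | frozenset[str],
) -> float:
    """Share of genome length on contigs without any marker hit."""
    if not contig_lengths:
        raise InputError("empty genome")
    unknown = set(marker_hit_contigs) - set(contig_lengths)
    if unknown:
        raise InputError(f"hit contigs not in genome: {sorted(unknown)}")
    total = sum(contig_lengths.values())
    if total <= 0:
        raise InputError("genome has zero length")
    silent = sum(
        length for contig, length in contig_lengths.items()
        if contig not in marker_hit_contigs
    )
    return silent / total


def consensus_lineage(lineages: Sequence[Lineage]) -> tuple[Lineage, list[str]]:
    """Strict consensus taxonomy of the chosen set's reference species.

    Returns the longest rank prefix on which every lineage agrees, stopping
    at the first disagreement, together with any warnings (an empty
    consensus is flagged).
    """
    if not lineages:
        raise InputError("no lineages to build a consensus from")
    consensus: list[tuple[str, str]] = []
    for level in range(min(len(lin) for lin in lineages)):
        entries = {lin[level] for lin in lineages}
        if len(entries) == 1:
            consensus.append(entries.pop())
        else:
            break
    warnings = []
    if not consensus:
        warnings.append("reference species disagree at the highest rank; no consensus lineage")
    return tuple(consensus), warnings


def marker_uniformity(
    contig_lengths: Mapping[str, int],
    marker_positions: Sequence[tuple[str, int]],
    fragment_size: int = 5000,
    n_steps: int | None = None,
    seed: int = 0,
) -> float:
    """Pearson correlation of cumulative sampled bases vs markers recovered.

    Non-overlapping ``fragment_size`` windows are drawn uniformly at random
    without replacement; after each draw the cumulative sampled length and
    the number of distinct markers recovered so far are recorded, and the
    Pearson correlation over that series is returned.  Uniformly distributed
    markers accumulate linearly with sampled bases (r near 1); clustered
    markers produce a noisy staircase and a lower r.

    ``n_steps`` defaults to every available window (the whole genome).
    """
    if not contig_lengths or sum(contig_lengths.values()) < fragment_size:
        raise InputError("genome shorter than one fragment")
    if len(marker_positions) < 2:
        raise InputError("need at least two markers")
    windows: list[tuple[str, int, int]] = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        for start in range(0, length, fragment_size):
            windows.append((contig, start, min(start + fragment_size, length)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(windows))
    if n_steps is not None:
        order = order[:n_steps]
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for idx, (contig, pos) in enumerate(marker_positions):
        by_contig.setdefault(contig, []).append((pos, idx))
    cum_bp = 0
    recovered: set[int] = set()
    xs: list[int] = []
    ys: list[int] = []
    for widx in order:
        contig, start, end = windows[widx]
        cum_bp += end - start
        for pos, idx in by_contig.get(contig, ()):
            if start <= pos < end:
                recovered.add(idx)
        xs.append(cum_bp)
        ys.append(len(recovered))
    if len(set(ys)) < 2:
        raise InputError("no variation in marker recovery; correlation undefined")
    return float(stats.pearsonr(xs, ys).statistic)
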