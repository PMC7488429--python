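"""End-to-end quality estimation of one query genome.

Wiring order: threshold the query's profile hits, place the hits against
the placement reference set (external jplace placements when supplied, the
built-in leaf-level fallback otherwise), resolve one best placement per
protein, choose the marker set whose clade encapsulates the most
placements, then score completeness and contamination of the query against
that set and report the consensus lineage of the set's reference species.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .db import MarkerDatabase
from .errors import TooFewMarkersError
from .hits import ProfileHit
from .quality import (
    QualityReport,
    consensus_lineage,
    estimate_quality,
    unassessed_fraction,
)
from .set_selection import (
    Placement,
    choose_marker_set,
    naive_place,
    resolve_best_placements,
)

DEFAULT_MIN_PLACEMENT_FRACTION = 0.2


def query_profile_counts(
    query_hits: Sequence[ProfileHit],
    thresholds: Mapping[str, float],
) -> tuple[dict[str, int], set[str]]:
    """Above-threshold copy counts per profile, plus the passing proteins."""
    proteins_by_profile: dict[str, set[str]] = {}
    passing: set[str] = set()
    for h in query_hits:
        cutoff = thresholds.get(h.profile_id)
        if cutoff is None or h.bit_score < cutoff:
            continue
        proteins_by_profile.setdefault(h.profile_id, set()).add(h.protein_id)
        passing.add(h.protein_id)
    return {p: len(v) for p, v in proteins_by_profile.items()}, passing


def estimate_genome_quality(
    query_hits: Sequence[ProfileHit],
    db: MarkerDatabase,
    placements: Sequence[Placement] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    protein_contigs: Mapping[str, str] | None = None,
    min_placement_fraction: float = DEFAULT_MIN_PLACEMENT_FRACTION,
) -> tuple[QualityReport, dict[str, Placement]]:
    """Score a query genome against the database.

    Returns the quality report together with the resolved per-protein
    placements (for the placements TSV).  Raises
    :class:`~magqc.errors.TooFewMarkersError` when no marker evidence
    survives thresholding, and :class:`~magqc.errors.NoMarkerSetError` when
    no clade set is applicable.
    """
    warnings: list[str] = []
    counts, passing_proteins = query_profile_counts(query_hits, db.thresholds)
    if not counts:
        raise TooFewMarkersError("no above-threshold marker hits in the query")

    if placements is None:
        reference_hits = [
            h for h in query_hits
            if h.profile_id in set(db.reference_profiles)
            and h.bit_score >= db.thresholds.get(h.profile_id, float("inf"))
        ]
        placements, naive_warnings = naive_place(reference_hits, db.reference_exemplars)
        warnings.extend(naive_warnings)
    if not placements:
        raise TooFewMarkersError(
            "no placements: the query matched no placement reference profile"
        )

    best = resolve_best_placements(placements, db.tree)
    choice = choose_marker_set(
        best,
        db.tree,
        db.sets,
        min_placement_fraction=min_placement_fraction,
        n_reference_profiles=len(db.reference_profiles),
    )
    warnings.extend(choice.warnings)
    chosen = db.set_by_id(choice.set_id)

    set_profiles = set(chosen.profile_ids)
    outside = sorted(set(counts) - set_profiles)
    if outside:
        warnings.append(
            f"{len(outside)} profile(s) with hits outside the chosen set ignored"
        )
    set_counts = {p: counts.get(p, 0) for p in chosen.profile_ids}
    completeness, contamination = estimate_quality(set_counts, chosen)

    lineage, lineage_warnings = consensus_lineage(
        [db.tree.lineages.get(g, ()) for g in chosen.species_ids]
    )
    warnings.extend(lineage_warnings)

    unassessed = None
    if contig_lengths is not None:
        hit_contigs = set()
        if protein_contigs:
            hit_contigs = {
                protein_contigs[p] for p in passing_proteins if p in protein_contigs
            }
        unassessed = unassessed_fraction(contig_lengths, hit_contigs)

    report = QualityReport(
        completeness=completeness,
        contamination=contamination,
        set_id=chosen.set_id,
        n_profiles_in_set=len(chosen),
        coverage_fraction=choice.coverage_fraction,
        lineage=lineage,
        unassessed_fraction=unassessed,
        profile_counts=set_counts,
        warnings=tuple(warnings),
    )
    return report, best
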