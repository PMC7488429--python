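"""Phylogenetic placement handling and marker-set selection.

Query proteins matching the placement reference set are placed on the
reference tree (externally, e.g. with pplacer, read from jplace; or with the
built-in leaf-level fallback).  Per protein the best-supported placement is
kept, and the clade-specific marker set whose clade encapsulates the largest
fraction of those placements is chosen.  When the lowest common ancestor of
the placements owns no set, the search ascends toward the root — the
highest-possible-ancestor rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InputError, NoMarkerSetError
from .hits import ProfileHit
from .reference_db import MarkerSet
from .tree import ReferenceTree

SUPPORT_FIELDS = ("post_prob", "posterior_probability", "like_weight_ratio")


@dataclass(frozen=True)
class Placement:
    """One candidate placement of a query protein on the reference tree."""

    protein_id: str
    node_id: str
    support: float

    def __post_init__(self) -> None:
        if not 0 <= self.support <= 1:
            raise InputError(f"placement support {self.support} outside [0, 1]")


@dataclass(frozen=True)
class SetChoice:
    """The selected marker set and how well it encapsulates the placements."""

    set_id: str
    node_id: str
    coverage_fraction: float
    n_placements: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _edge_leafsets(newick: str) -> dict[int, frozenset[str]]:
    """Leaf set below each jplace-numbered edge of an annotated Newick.

    jplace embeds its reference tree with ``{N}`` edge numbers after branch
    lengths; this tokenizer records, for every edge number, the set of leaf
    labels in the subtree the edge subtends.
    """
    s = newick.strip().rstrip(";")
    out: dict[int, frozenset[str]] = {}
    stack: list[list[frozenset[str]]] = []
    last: frozenset[str] | None = None
    after_close = False
    i = 0
    while i < len(s):
        c = s[i]
        if c == "(":
            stack.append([])
            after_close = False
            i += 1
        elif c == ")":
            kids = stack.pop()
            last = frozenset().union(*kids) if kids else frozenset()
            if stack:
                stack[-1].append(last)
            after_close = True
            i += 1
        elif c == ",":
            after_close = False
            i += 1
        elif c == ":":
            i += 1
            while i < len(s) and s[i] not in ",(){};":
                i += 1
        elif c == "{":
            j = s.index("}", i)
            if last is None:
                raise InputError("edge number with no preceding node")
            out[int(s[i + 1 : j])] = last
            i = j + 1
        else:
            j = i
            while j < len(s) and s[j] not in ":,(){};":
                j += 1
            label = s[i:j].strip().strip("'\"")
            if label and not after_close:
                last = frozenset([label])
                if stack:
                    stack[-1].append(last)
            i = j
    return out


def parse_placements(
    document: Mapping | str | Path,
    tree: ReferenceTree,
) -> list[Placement]:
    """Read a jplace (version 3) document against a reference tree.

    Edge numbers in the embedded tree are resolved to reference-tree nodes
    by leaf-set identity (the node below the numbered edge).  Support is
    taken from a posterior-probability field when the document declares one,
    falling back to the likelihood weight ratio.
    """
    if isinstance(document, (str, Path)):
        document = json.loads(Path(document).read_text())
    fields = document.get("fields")
    if not fields:
        raise InputError("jplace document lacks a fields declaration")
    if "edge_num" not in fields:
        raise InputError(f"no edge_num field; available fields: {fields}")
    support_field = next((f for f in SUPPORT_FIELDS if f in fields), None)
    if support_field is None:
        raise InputError(f"no support field; available fields: {fields}")
    edge_idx = fields.index("edge_num")
    support_idx = fields.index(support_field)

    edge_to_node: dict[int, str] = {}
    for edge, leaves in _edge_leafsets(document["tree"]).items():
        node_id = tree.node_by_leafset(leaves)
        if node_id is None:
            raise InputError(
                f"jplace edge {edge} subtends leaves absent from the reference tree"
            )
        edge_to_node[edge] = node_id

    placements: list[Placement] = []
    for entry in document.get("placements", []):
        if "n" in entry:
            names = list(entry["n"])
        elif "nm" in entry:
            names = [nm[0] for nm in entry["nm"]]
        else:
            raise InputError("placement entry lacks 'n'/'nm' name field")
        for name in names:
            for row in entry["p"]:
                edge = int(row[edge_idx])
                if edge not in edge_to_node:
                    raise InputError(f"placement on unknown edge {edge}")
                placements.append(
                    Placement(str(name), edge_to_node[edge], float(row[support_idx]))
                )
    return placements


def resolve_best_placements(
    placements: Iterable[Placement],
    tree: ReferenceTree,
) -> dict[str, Placement]:
    """Keep, per protein, the single best-supported placement.

    Ties on support are broken toward the location closer to the root (the
    conservative choice: it never over-commits to a narrow clade), then by
    node id for determinism.
    """
    best: dict[str, Placement] = {}
    for p in placements:
        cur = best.get(p.protein_id)
        if cur is None:
            best[p.protein_id] = p
            continue
        key = (-p.support, tree.depth[p.node_id], p.node_id)
        cur_key = (-cur.support, tree.depth[cur.node_id], cur.node_id)
        if key < cur_key:
            best[p.protein_id] = p
    return best


def choose_marker_set(
    best_placements: Mapping[str, Placement],
    tree: ReferenceTree,
    sets: Sequence[MarkerSet],
    min_placement_fraction: float = 0.0,
    n_reference_profiles: int | None = None,
) -> SetChoice:
    """Select the marker set whose clade encapsulates the most placements.

    Candidates are every set whose clade contains at least one best
    placement, plus — for the lowest common ancestor of all placements —
    the nearest ancestor owning a set (the highest-possible-ancestor rule,
    which guarantees a candidate whenever any ancestor of the LCA owns a
    set).  The winner maximises the number of encapsulated placements; ties
    go to the deeper (more specific) node, then to the set id.  Coverage
    below 1 is reported with a warning rather than refused.
    """
    if not best_placements:
        raise InputError("no placements to choose a set from")
    if not sets:
        raise NoMarkerSetError("no marker sets defined on the tree")
    sets_by_node: dict[str, MarkerSet] = {}
    for s in sets:
        if s.node_id in sets_by_node:
            raise InputError(f"multiple sets attached to node {s.node_id}")
        sets_by_node[s.node_id] = s

    placement_nodes = [p.node_id for p in best_placements.values()]
    n = len(placement_nodes)

    def encapsulated(node_id: str) -> int:
        return sum(1 for pn in placement_nodes if tree.is_within(pn, node_id))

    candidates: dict[str, int] = {}
    for node_id in sets_by_node:
        count = encapsulated(node_id)
        if count > 0:
            candidates[node_id] = count
    lca = tree.lca(placement_nodes)
    for anc in tree.ancestors(lca, include_self=True):
        if anc in sets_by_node:
            candidates.setdefault(anc, encapsulated(anc))
            break
    if not candidates:
        raise NoMarkerSetError("no applicable marker set for these placements")

    chosen_node = min(
        candidates,
        key=lambda nid: (-candidates[nid], -tree.depth[nid], sets_by_node[nid].set_id),
    )
    chosen = sets_by_node[chosen_node]
    coverage = candidates[chosen_node] / n
    warnings: list[str] = []
    if coverage < 1:
        warnings.append(
            f"chosen set {chosen.set_id} encapsulates only "
            f"{candidates[chosen_node]}/{n} placements"
        )
    if n_reference_profiles:
        placed_fraction = n / n_reference_profiles
        if placed_fraction < min_placement_fraction:
            warnings.append(
                f"only {n}/{n_reference_profiles} reference profiles produced "
                "placements; the set choice rests on weak evidence and the "
                "genome deserves closer inspection"
            )
    return SetChoice(
        set_id=chosen.set_id,
        node_id=chosen_node,
        coverage_fraction=coverage,
        n_placements=n,
        warnings=tuple(warnings),
    )


def naive_place(
    query_hits: Iterable[ProfileHit],
    profile_exemplars: Mapping[str, str],
) -> tuple[list[Placement], list[str]]:
    """Built-in fallback placement at reference leaves.

    Each query protein is assigned to its best-scoring reference-set profile
    and placed, with support 1.0, on the leaf of that profile's exemplar
    genome (the reference genome whose marker protein scores highest).
    Proteins whose profile has no exemplar are skipped with a warning.  This
    is a deliberately crude stand-in for model-based phylogenetic placement,
    sufficient to drive set selection when no jplace file is supplied.
    """
    best_hit: dict[str, ProfileHit] = {}
    for h in query_hits:
        cur = best_hit.get(h.protein_id)
        if cur is None or (-h.bit_score, h.profile_id) < (-cur.bit_score, cur.profile_id):
            best_hit[h.protein_id] = h
    placements: list[Placement] = []
    warnings: list[str] = []
    for protein_id in sorted(best_hit):
        hit = best_hit[protein_id]
        genome = profile_exemplars.get(hit.profile_id)
        if genome is None:
            warnings.append(
                f"protein {protein_id}: no reference exemplar for profile "
                f"{hit.profile_id}; skipped"
            )
            continue
        placements.append(Placement(protein_id, genome, 1.0))
    return placements, warnings


def write_placements_tsv(
    best_placements: Mapping[str, Placement],
    path: str | Path,
) -> None:
    """Per-placement node assignments (the plotting surrogate)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tnode_id\tsupport\n")
        for protein_id in sorted(best_placements):
            p = best_placements[protein_id]
            fh.write(f"{p.protein_id}\t{p.node_id}\t{p.support}\n")
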