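"""Rooted reference tree over genome identifiers.

The reference tree is the backbone of set selection: each internal node may
own a clade-specific single-copy marker gene set, and query placements are
resolved against node clades.  :class:`ReferenceTree` wraps a rooted
:class:`dendropy.Tree`, assigning every node a deterministic identifier
(leaves keep their genome label, internal nodes are numbered ``n0, n1, ...``
in preorder) so that node references are stable across Newick round-trips.

Per-leaf NCBI-style lineages (ordered ``rank:name`` pairs) ride along with
the tree and feed the consensus-lineage report.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .errors import InputError

Lineage = tuple[tuple[str, str], ...]


def parse_lineage(text: str) -> Lineage:
    """Parse ``rank:name;rank:name;...`` into an ordered lineage."""
    out = []
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise InputError(f"bad lineage element {part!r} (expected rank:name)")
        rank, name = part.split(":", 1)
        out.append((rank.strip(), name.strip()))
    return tuple(out)


def format_lineage(lineage: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{rank}:{name}" for rank, name in lineage)


class ReferenceTree:
    """Rooted tree with deterministic node ids, clade caches and lineages."""

    def __init__(
        self,
        tree: dendropy.Tree,
        lineages: Mapping[str, Lineage] | None = None,
    ) -> None:
        self._tree = tree
        self._assign_ids()
        self.lineages: dict[str, Lineage] = dict(lineages or {})

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        lineages: Mapping[str, Lineage] | None = None,
    ) -> "ReferenceTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise InputError(f"malformed Newick: {exc}") from exc
        return cls(tree, lineages)

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        lineages: Mapping[str, Lineage] | None = None,
    ) -> "ReferenceTree":
        return cls.from_newick(Path(path).read_text(), lineages)

    def _assign_ids(self) -> None:
        self.nodes: dict[str, dendropy.Node] = {}
        self.parent: dict[str, str | None] = {}
        self.depth: dict[str, int] = {}
        self.leaves_below: dict[str, frozenset[str]] = {}
        self._id_of: dict[int, str] = {}
        counter = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise InputError("tree has an unlabelled leaf")
                node_id = node.taxon.label
                if node_id in self.nodes:
                    raise InputError(f"duplicate leaf label {node_id!r}")
            else:
                node_id = f"n{counter}"
                counter += 1
            self.nodes[node_id] = node
            self._id_of[id(node)] = node_id
            parent = node.parent_node
            pid = self._id_of[id(parent)] if parent is not None else None
            self.parent[node_id] = pid
            self.depth[node_id] = 0 if pid is None else self.depth[pid] + 1
        # postorder pass for clade leaf sets
        for node in self._tree.postorder_node_iter():
            node_id = self._id_of[id(node)]
            if node.is_leaf():
                self.leaves_below[node_id] = frozenset([node_id])
            else:
                self.leaves_below[node_id] = frozenset().union(
                    *(self.leaves_below[self._id_of[id(c)]] for c in node.child_nodes())
                )

    # -- queries ----------------------------------------------------------

    @property
    def root_id(self) -> str:
        return self._id_of[id(self._tree.seed_node)]

    def leaf_ids(self) -> list[str]:
        return sorted(self.leaves_below[self.root_id])

    def internal_ids(self) -> list[str]:
        return [i for i, n in self.nodes.items() if not n.is_leaf()]

    def is_leaf(self, node_id: str) -> bool:
        return self.nodes[node_id].is_leaf()

    def ancestors(self, node_id: str, include_self: bool = False) -> list[str]:
        """Ancestor ids from ``node_id`` toward the root."""
        out = [node_id] if include_self else []
        cur = self.parent[node_id]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def is_within(self, node_id: str, ancestor_id: str) -> bool:
        """True if ``node_id`` lies in the clade rooted at ``ancestor_id``."""
        return node_id == ancestor_id or ancestor_id in self.ancestors(node_id)

    def lca(self, node_ids: Sequence[str]) -> str:
        """Lowest common ancestor of a non-empty set of nodes."""
        if not node_ids:
            raise InputError("lca of empty node set")
        paths = [list(reversed(self.ancestors(n, include_self=True))) for n in node_ids]
        lca = paths[0][0]
        for level in range(min(len(p) for p in paths)):
            tier = {p[level] for p in paths}
            if len(tier) == 1:
                lca = tier.pop()
            else:
                break
        return lca

    def node_by_leafset(self, leaves: frozenset[str]) -> str | None:
        for node_id, below in self.leaves_below.items():
            if below == leaves:
                return node_id
        return None

    # -- serialisation ----------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def to_jplace_tree(self) -> tuple[str, dict[int, str]]:
        """Newick with ``{edge}`` annotations plus the edge->node-id map.

        Edge numbers follow jplace convention: the number attached after a
        node's branch length designates the edge above that node.
        """
        edge_map: dict[int, str] = {}
        counter = [0]

        def render(node: dendropy.Node) -> str:
            node_id = self._id_of[id(node)]
            if node.is_leaf():
                body = node_id
            else:
                body = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
            length = node.edge.length if node.edge.length is not None else 0.1
            edge = counter[0]
            counter[0] += 1
            edge_map[edge] = node_id
            return f"{body}:{length}{{{edge}}}"

        return render(self._tree.seed_node) + ";", edge_map


def read_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Read a TSV of ``genome_id<TAB>rank:name;rank:name;...``."""
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("genome_id\t"):
                continue
            try:
                genome, text = line.split("\t", 1)
            except ValueError:
                raise InputError(f"bad lineage line: {line!r}") from None
            lineages[genome] = parse_lineage(text)
    return lineages


def write_lineage_table(lineages: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tlineage\n")
        for genome in sorted(lineages):
            fh.write(f"{genome}\t{format_lineage(lineages[genome])}\n")
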