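"""Gene-tree container and Newick I/O.

The algorithms in :mod:`ggfam.events` and :mod:`ggfam.parsimony` operate on a
minimal mutable node structure; Newick parsing is delegated to dendropy and
the result converted.  Event labels round-trip through NHX comment blocks
(``[&&NHX:Ev=D]`` / ``[&&NHX:Ev=S]``).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy


class Event(enum.Enum):
    DUPLICATION = "D"
    SPECIATION = "S"
    LEAF = "L"
    UNSET = "?"


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    children: list["Node"] = field(default_factory=list)
    species: str | None = None
    event: Event = Event.UNSET

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "Node":
        return Node(
            label=self.label,
            length=self.length,
            children=[c.copy() for c in self.children],
            species=self.species,
            event=self.event,
        )


@dataclass
class GeneTree:
    """A rooted gene tree. Leaf labels must be unique."""

    root: Node

    def __post_init__(self):
        labels = self.root.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf label(s): {dupes}")

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def postorder(self):
        return self.root.postorder()

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def copy(self) -> "GeneTree":
        return GeneTree(root=self.root.copy())

    def node_ids(self) -> dict[int, str]:
        """Stable readable ids: leaf label for tips, ``n<i>`` (postorder) else."""
        ids = {}
        i = 0
        for n in self.postorder():
            if n.is_leaf:
                ids[id(n)] = n.label
            else:
                ids[id(n)] = f"n{i}"
                i += 1
        return ids


def parse_newick(source: str | Path) -> GeneTree:
    """Parse a Newick string or file into a :class:`GeneTree`.

    NHX ``Ev=`` annotations, if present, are restored onto node events.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(") and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as e:  # dendropy raises various error types
        raise ValueError(f"invalid Newick: {e}") from e

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for comment in dnode.comments or []:
            if "&&NHX" in comment:
                for part in comment.split(":"):
                    if part.startswith("Ev="):
                        node.event = Event(part[3:])
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return GeneTree(root=convert(dtree.seed_node))


def write_newick(tree: GeneTree, include_events: bool = False) -> str:
    """Serialize a tree; inverse of :func:`parse_newick` up to whitespace."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += node.label
        if node.length is not None:
            s += f":{node.length:g}"
        if include_events and not node.is_leaf and node.event in (
            Event.DUPLICATION,
            Event.SPECIATION,
        ):
            s += f"[&&NHX:Ev={node.event.value}]"
        return s

    return fmt(tree.root) + ";"


@dataclass
class SpeciesMap:
    """Resolve a gene label to a species id.

    Either an explicit ``table`` (always wins) or a label pattern: split the
    label on ``delimiter`` and take field ``field`` (default: the prefix
    before the first underscore).
    """

    table: dict[str, str] | None = None
    delimiter: str = "_"
    field_index: int = 0

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesMap":
        table = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            table[parts[0].strip()] = parts[1].strip()
        return cls(table=table)

    def resolve(self, label: str) -> str:
        if self.table is not None:
            if label not in self.table:
                raise KeyError(f"leaf {label!r} missing from species map")
            return self.table[label]
        parts = label.split(self.delimiter)
        if len(parts) <= self.field_index:
            raise KeyError(
                f"leaf {label!r}: cannot extract field {self.field_index} "
                f"with delimiter {self.delimiter!r}"
            )
        return parts[self.field_index]

    def apply(self, tree: GeneTree) -> None:
        """Set ``species`` on every leaf in place."""
        for leaf in tree.leaves():
            leaf.species = self.resolve(leaf.label)


def resolve_polytomies(tree: GeneTree) -> GeneTree:
    """Deterministically binarize multifurcations (first-two grouping)."""
    out = tree.copy()
    for node in list(out.postorder()):
        while len(node.children) > 2:
            a, b = node.children[0], node.children[1]
            merged = Node(children=[a, b], length=0.0)
            node.children = [merged] + node.children[2:]
    return out
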