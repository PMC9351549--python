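"""Typed directed heterogeneous information networks (knowledge graphs).

A schema fixes the allowed node types and typed relations; the graph maps
each node to a type (the pair ``(concept id, type)`` *is* the node identity,
so a concept id carrying two semantic types yields two distinct nodes) and
stores a deduplicated set of typed edges.  Both traversal directions are
indexed by ``(node, relation, neighbor type)`` so that the typed
neighborhood of a node is available in average constant time — the data
structure is built entirely from hash maps, never from edge-set scans.

Triple files are UTF-8 tab-separated with columns
``SUBJECT_ID  SUBJECT_TYPE  PREDICATE  OBJECT_ID  OBJECT_TYPE`` (extra
columns ignored, ``#`` comments skipped, an optional header is detected by a
non-identifier first field).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "Node",
    "Relation",
    "Schema",
    "KnowledgeGraph",
    "TripleFormatError",
    "SchemaViolationError",
    "load_triples",
    "save_triples",
]


class TripleFormatError(ValueError):
    """A triple file row that cannot be parsed; carries its line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class SchemaViolationError(ValueError):
    """An edge whose (relation, source type, target type) is not in the schema."""


class Node(NamedTuple):
    """A graph node: a concept identifier together with its type label."""

    id: str
    type: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.id}[{self.type}]"


class Relation(NamedTuple):
    """A typed relation: label plus its source and target node types."""

    label: str
    source_type: str
    target_type: str


@dataclass(frozen=True)
class Schema:
    """The allowed node types and typed relations of a network.

    Invariants: every relation endpoint type is a declared node type, and
    more than one node type exists.
    """

    node_types: frozenset[str]
    relations: frozenset[Relation]

    def __post_init__(self) -> None:
        if len(self.node_types) <= 1:
            raise ValueError("a schema requires more than one node type")
        for rel in self.relations:
            if rel.source_type not in self.node_types or rel.target_type not in self.node_types:
                raise ValueError(f"relation {rel} uses an undeclared node type")

    def allows(self, label: str, source_type: str, target_type: str) -> bool:
        return Relation(label, source_type, target_type) in self.relations

    @classmethod
    def from_relations(cls, relations: Iterable[tuple[str, str, str]]) -> "Schema":
        rels = frozenset(Relation(*r) for r in relations)
        types = frozenset(t for r in rels for t in (r.source_type, r.target_type))
        return cls(node_types=types, relations=rels)


Edge = tuple[Node, str, Node]


class KnowledgeGraph:
    """A schema-conformant typed directed graph with typed-neighbor indexes.

    Edges form a set (duplicate triples collapse) and are unweighted, matching
    a binary adjacency matrix per relation.  Backward traversal uses the
    incoming-edge index; inverse relations are never materialized.
    """

    def __init__(self, schema: Schema):
        self.schema = schema
        self._nodes: dict[Node, str] = {}
        self._edges: set[Edge] = set()
        self._out: dict[tuple[Node, str, str], set[Node]] = {}
        self._in: dict[tuple[Node, str, str], set[Node]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> Node:
        if node.type not in self.schema.node_types:
            raise SchemaViolationError(f"node type {node.type!r} not in schema")
        self._nodes[node] = node.type
        return node

    def add_edge(self, source: Node, label: str, target: Node) -> None:
        if not self.schema.allows(label, source.type, target.type):
            raise SchemaViolationError(
                f"relation ({label!r}: {source.type!r} -> {target.type!r}) not in schema"
            )
        self.add_node(source)
        self.add_node(target)
        edge = (source, label, target)
        if edge in self._edges:
            return
        self._edges.add(edge)
        self._out.setdefault((source, label, target.type), set()).add(target)
        self._in.setdefault((target, label, source.type), set()).add(source)

    # -- inspection ---------------------------------------------------

    @property
    def nodes(self) -> dict[Node, str]:
        return self._nodes

    @property
    def edges(self) -> set[Edge]:
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_node(self, node: Node) -> bool:
        return node in self._nodes

    def node(self, id: str, type: str) -> Node:
        """Return the node handle for ``(id, type)``, raising if absent."""
        node = Node(id, type)
        if node not in self._nodes:
            raise KeyError(f"unknown node {node}")
        return node

    def nodes_of_type(self, type: str) -> list[Node]:
        return sorted(n for n in self._nodes if n.type == type)

    # -- typed neighborhoods ------------------------------------------

    def out_neighbors(self, u: Node, relation: str, neighbor_type: str) -> set[Node]:
        """Out-neighbors of ``u`` along ``relation`` restricted to a type.

        Average constant-time hash lookup; unknown relations or types give the
        empty set, an unknown node raises ``KeyError``.
        """
        if u not in self._nodes:
            raise KeyError(f"unknown node {u}")
        return set(self._out.get((u, relation, neighbor_type), ()))

    def in_neighbors(self, v: Node, relation: str, neighbor_type: str) -> set[Node]:
        """In-neighbors of ``v`` along ``relation`` restricted to a type."""
        if v not in self._nodes:
            raise KeyError(f"unknown node {v}")
        return set(self._in.get((v, relation, neighbor_type), ()))

    def out_degree(self, u: Node, relation: str, neighbor_type: str) -> int:
        if u not in self._nodes:
            raise KeyError(f"unknown node {u}")
        return len(self._out.get((u, relation, neighbor_type), ()))

    # -- integrity ----------------------------------------------------

    def rebuild_indexes(self) -> tuple[dict, dict]:
        """Recompute both indexes from the edge set (consistency check)."""
        out: dict[tuple[Node, str, str], set[Node]] = {}
        inn: dict[tuple[Node, str, str], set[Node]] = {}
        for source, label, target in self._edges:
            out.setdefault((source, label, target.type), set()).add(target)
            inn.setdefault((target, label, source.type), set()).add(source)
        return out, inn

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        for source, label, target in self._edges:
            if source not in self._nodes or target not in self._nodes:
                raise ValueError(f"dangling edge ({source}, {label}, {target})")
            if not self.schema.allows(label, source.type, target.type):
                raise SchemaViolationError(
                    f"edge ({source}, {label}, {target}) violates schema"
                )
        out, inn = self.rebuild_indexes()
        if out != self._out or inn != self._in:
            raise ValueError("neighbor indexes inconsistent with edge set")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:  # pragma: no cover
        return f"KnowledgeGraph({self.n_nodes} nodes, {self.n_edges} edges)"


# -- triple file I/O ------------------------------------------------------

_COLUMNS = ("SUBJECT_ID", "SUBJECT_TYPE", "PREDICATE", "OBJECT_ID", "OBJECT_TYPE")


def _parse_rows(handle: Iterator[str]) -> Iterator[tuple[int, tuple[str, str, str, str, str]]]:
    for line_number, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if line_number == 1 and fields[0].strip().upper() in {_COLUMNS[0], "SUBJECT"}:
            continue  # header row: first field is a column name, not an identifier
        if len(fields) < 5:
            raise TripleFormatError(
                f"expected >=5 tab-separated columns, found {len(fields)}", line_number
            )
        values = tuple(f.strip() for f in fields[:5])
        if any(not v for v in values):
            raise TripleFormatError("empty field in triple row", line_number)
        yield line_number, values  # type: ignore[misc]


def load_triples(
    path: str | Path | io.TextIOBase,
    schema: Schema | None = None,
) -> KnowledgeGraph:
    """Read a triple TSV into a graph.

    With a declared ``schema`` every row must conform to it; without one the
    schema is inferred as exactly the observed (relation, types) combinations.
    Duplicate rows collapse to a single edge.  An empty file with an inferred
    schema yields a graph over a minimal two-type placeholder schema.
    """
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8") as handle:
            rows = [r for _, r in _parse_rows(handle)]
    else:
        rows = [r for _, r in _parse_rows(path)]

    if schema is None:
        observed = {(pred, s_type, o_type) for s_id, s_type, pred, o_id, o_type in rows}
        if observed:
            schema = Schema.from_relations(observed)
        else:  # an empty file still needs a (legal) schema: |A| > 1
            schema = Schema(frozenset({"_A", "_B"}), frozenset())

    graph = KnowledgeGraph(schema)
    for s_id, s_type, pred, o_id, o_type in rows:
        if not schema.allows(pred, s_type, o_type):
            raise SchemaViolationError(
                f"row ({s_id}, {s_type}, {pred}, {o_id}, {o_type}) "
                "conflicts with the declared schema"
            )
        graph.add_edge(Node(s_id, s_type), pred, Node(o_id, o_type))
    return graph


def save_triples(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write the graph as a triple TSV, sorted for reproducible diffs."""
    lines = sorted(
        (s.id, s.type, label, o.id, o.type) for s, label, o in graph.edges
    )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_COLUMNS) + "\n")
        for row in lines:
            handle.write("\t".join(row) + "\n")
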