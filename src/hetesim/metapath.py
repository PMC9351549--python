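"""Metapaths: typed walk signatures, their instances, and half-splitting.

A metapath alternates node types and relation labels,
``A1-[R1]->A2-...-[Rl]->A(l+1)``.  Length 0 denotes the self-relation
(identity).  Scoring decomposes a metapath into two halves meeting at a
central entity set: for even length the halves share the central node type;
for odd length the central entities are the *edge instances* of the middle
relation, which realizes the classical construction of materializing one
bridge node per middle edge without mutating the graph (each such bridge has
exactly one in- and one out-edge, so walk probabilities are unchanged).

Enumeration finds every metapath (type signature of a directed walk, node
revisits allowed — the semantics of the transition-matrix product) with an
instance from some source to the target, in deterministic sorted order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .hin import KnowledgeGraph, Node

__all__ = ["Metapath", "MetapathSplit", "enumerate_metapaths", "instances", "split"]


@dataclass(frozen=True, order=True)
class Metapath:
    """An alternating sequence of node types and relation labels."""

    node_types: tuple[str, ...]
    relations: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.node_types) != len(self.relations) + 1:
            raise ValueError("a metapath over l relations needs l+1 node types")

    @property
    def length(self) -> int:
        return len(self.relations)

    @property
    def source_type(self) -> str:
        return self.node_types[0]

    @property
    def target_type(self) -> str:
        return self.node_types[-1]

    def reverse(self) -> "Metapath":
        """The same metapath traversed target-to-source."""
        return Metapath(self.node_types[::-1], self.relations[::-1])

    def concat(self, other: "Metapath") -> "Metapath":
        if self.node_types[-1] != other.node_types[0]:
            raise ValueError("cannot concatenate: central types differ")
        return Metapath(
            self.node_types + other.node_types[1:], self.relations + other.relations
        )

    def __str__(self) -> str:
        if not self.relations:
            return self.node_types[0]
        parts = [self.node_types[0]]
        for rel, node_type in zip(self.relations, self.node_types[1:]):
            parts.append(f"-[{rel}]->{node_type}")
        return "".join(parts)

    @classmethod
    def parse(cls, text: str) -> "Metapath":
        """Parse the ``A1-[R1]->A2`` serialization form."""
        chunks = text.split("-[")
        node_types = [chunks[0].strip()]
        relations = []
        for chunk in chunks[1:]:
            try:
                rel, node_type = chunk.split("]->")
            except ValueError as exc:
                raise ValueError(f"malformed metapath text {text!r}") from exc
            relations.append(rel.strip())
            node_types.append(node_type.strip())
        return cls(tuple(node_types), tuple(relations))


@dataclass(frozen=True)
class MetapathSplit:
    """A metapath cut at its center for two-sided probability propagation.

    ``central_kind`` is ``"node-type"`` for even length (the halves share the
    central node type) and ``"middle-edge"`` for odd length (the central
    entities are instances of ``middle_relation``; ``left``/``right`` are the
    halves strictly before/after that relation).
    """

    left: Metapath
    right: Metapath
    central_kind: str
    middle_relation: str | None = None

    def join(self) -> Metapath:
        """Invert the split, recovering the original metapath."""
        if self.central_kind == "node-type":
            return self.left.concat(self.right)
        bridge = Metapath(
            (self.left.node_types[-1], self.right.node_types[0]),
            (self.middle_relation,),
        )
        return self.left.concat(bridge).concat(self.right)


def split(metapath: Metapath) -> MetapathSplit:
    """Split a metapath of length >= 1 into left/right halves.

    Even length l gives two halves of length l/2 sharing the central node
    type; odd length cuts out the middle relation, whose edge instances act
    as the central entities.
    """
    l = metapath.length
    if l < 1:
        raise ValueError("cannot split a length-0 metapath")
    if l % 2 == 0:
        half = l // 2
        left = Metapath(metapath.node_types[: half + 1], metapath.relations[:half])
        right = Metapath(metapath.node_types[half:], metapath.relations[half:])
        return MetapathSplit(left, right, "node-type")
    mid = (l - 1) // 2  # index of the middle relation
    left = Metapath(metapath.node_types[: mid + 1], metapath.relations[:mid])
    right = Metapath(metapath.node_types[mid + 1 :], metapath.relations[mid + 1 :])
    return MetapathSplit(left, right, "middle-edge", metapath.relations[mid])


def instances(
    graph: KnowledgeGraph, s: Node, t: Node, metapath: Metapath
) -> list[tuple[Node, ...]]:
    """All walks from ``s`` to ``t`` realizing ``metapath`` (revisits allowed).

    The length-0 metapath is the self-relation: ``[[s]]`` when ``s == t``,
    else no instance.
    """
    if s.type != metapath.source_type or t.type != metapath.target_type:
        raise ValueError(
            f"endpoint types ({s.type}, {t.type}) do not match metapath {metapath}"
        )
    if metapath.length == 0:
        return [(s,)] if s == t else []

    # prune forward expansion by backward reachability: reach_t[j] holds the
    # nodes from which t is reachable in exactly j remaining steps
    l = metapath.length
    reach_t: list[set[Node]] = [set() for _ in range(l + 1)]
    reach_t[0] = {t}
    for j in range(1, l + 1):
        rel = metapath.relations[l - j]
        a_type = metapath.node_types[l - j]
        frontier: set[Node] = set()
        for v in reach_t[j - 1]:
            frontier |= graph.in_neighbors(v, rel, a_type)
        reach_t[j] = frontier

    out: list[tuple[Node, ...]] = []

    def extend(prefix: list[Node], step: int) -> None:
        if step == l:
            if prefix[-1] == t:
                out.append(tuple(prefix))
            return
        rel = metapath.relations[step]
        next_type = metapath.node_types[step + 1]
        for nxt in sorted(graph.out_neighbors(prefix[-1], rel, next_type)):
            if nxt in reach_t[l - step - 1]:
                extend(prefix + [nxt], step + 1)

    if s in reach_t[l]:
        extend([s], 0)
    return out


def enumerate_metapaths(
    graph: KnowledgeGraph,
    sources: set[Node],
    target: Node,
    max_length: int,
) -> list[Metapath]:
    """Every metapath of length <= ``max_length`` with an instance joining
    some source to the target, sorted and deduplicated.

    Enumeration is over type signatures, not walks: the search state pairs a
    signature prefix with the *set* of nodes reachable from the sources via
    that prefix, so shared signatures are expanded once.  Expansion is pruned
    by backward reachability from the target.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    if max_length > 4:
        warnings.warn(
            "metapaths longer than 4 are permitted, but pruned HeteSim is "
            "no longer guaranteed to equal plain HeteSim there",
            stacklevel=2,
        )
    if target not in graph.nodes:
        raise KeyError(f"unknown target node {target}")
    for s in sources:
        if s not in graph.nodes:
            raise KeyError(f"unknown source node {s}")

    # nodes that can reach the target in exactly j steps, for j <= max_length
    reach_t: list[set[Node]] = [set() for _ in range(max_length + 1)]
    reach_t[0] = {target}
    relations = sorted(graph.schema.relations)
    for j in range(1, max_length + 1):
        frontier: set[Node] = set()
        for v in reach_t[j - 1]:
            for rel in relations:
                if rel.target_type == v.type:
                    frontier |= graph.in_neighbors(v, rel.label, rel.source_type)
        reach_t[j] = frontier
    can_reach = [set().union(*reach_t[: j + 1]) for j in range(max_length + 1)]

    found: set[Metapath] = set()

    def expand(prefix: Metapath, frontier: set[Node], used: int) -> None:
        if target in frontier and used >= 1:
            found.add(prefix)
        if used == max_length:
            return
        remaining = max_length - used
        # group next hops by (relation, neighbor type)
        by_sig: dict[tuple[str, str], set[Node]] = {}
        for u in frontier:
            for rel in relations:
                if rel.source_type != u.type:
                    continue
                for v in graph.out_neighbors(u, rel.label, rel.target_type):
                    if v in can_reach[remaining - 1]:
                        by_sig.setdefault((rel.label, rel.target_type), set()).add(v)
        for (label, node_type), nxt in sorted(by_sig.items(), key=lambda kv: kv[0]):
            expand(
                Metapath(prefix.node_types + (node_type,), prefix.relations + (label,)),
                nxt,
                used + 1,
            )

    by_type: dict[str, set[Node]] = {}
    for s in sources:
        by_type.setdefault(s.type, set()).add(s)
    for source_type in sorted(by_type):
        starters = {s for s in by_type[source_type] if s in can_reach[max_length]}
        if starters:
            expand(Metapath((source_type,), ()), starters, 0)
    return sorted(found, key=lambda p: (p.length, p.node_types, p.relations))
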