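"""Deterministic HeteSim via sparse probability propagation.

HeteSim scores the relatedness of a source ``s`` and target ``t`` along a
metapath ``P`` as the cosine of two reach-probability vectors: the chance a
uniform random walk along the left half of ``P`` from ``s`` ends at each
central entity, and the mirror quantity walking the right half backwards
from ``t``.  These vectors are the relevant rows of the reachable
probability matrix (the product of row-normalized typed adjacency
matrices), but are computed here as sparse dictionaries layer by layer —
no matrices are ever formed, which is what makes the computation fast on
large, sparse biomedical graphs.

Probability mass that reaches a node with no eligible continuation (a dead
end) is dropped, so a half-walk profile sums to at most 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping

from .hin import KnowledgeGraph, Node
from .metapath import Metapath, MetapathSplit, split

__all__ = [
    "ReachProfile",
    "HeteSimScore",
    "propagate",
    "left_profile",
    "right_profile",
    "hetesim",
    "cosine",
]

#: central entities are nodes (even length) or middle-relation edges (odd)
CentralEntity = Hashable


@dataclass(frozen=True)
class ReachProfile:
    """Sparse end-of-half-walk probability masses for one side.

    ``masses`` maps each reached central entity to the probability that a
    uniform random walk along the half-metapath ends there.  The total is 1
    minus the probability of hitting a dead end, hence at most 1.
    """

    masses: dict[CentralEntity, float]
    side: str  # "left" | "right"
    step: int  # number of relation steps propagated

    @property
    def total_mass(self) -> float:
        return math.fsum(self.masses.values())

    @property
    def norm(self) -> float:
        return math.sqrt(math.fsum(m * m for m in self.masses.values()))


@dataclass(frozen=True)
class HeteSimScore:
    """A HeteSim value in [0, 1]; ``defined`` is False when either side's
    reach profile is empty (no central entity reachable), in which case the
    value is 0 by convention so that such pairs rank below any positive
    score."""

    value: float
    defined: bool = True

    def as_record(self, source: Node, target: Node, metapath: Metapath) -> dict:
        return {
            "source": list(source),
            "target": list(target),
            "metapath": str(metapath),
            "score": self.value,
            "defined": self.defined,
        }


def cosine(left: Mapping[CentralEntity, float], right: Mapping[CentralEntity, float]) -> float:
    """Cosine of two sparse nonnegative vectors over the union support.

    Zero vectors give 0.  The result is clipped into [0, 1] to absorb
    floating-point overshoot.
    """
    dot = math.fsum(mass * right.get(key, 0.0) for key, mass in left.items())
    norm_l = math.sqrt(math.fsum(m * m for m in left.values()))
    norm_r = math.sqrt(math.fsum(m * m for m in right.values()))
    if norm_l == 0.0 or norm_r == 0.0:
        return 0.0
    return min(1.0, max(0.0, dot / (norm_l * norm_r)))


def _spread(
    graph: KnowledgeGraph,
    masses: dict[Node, float],
    relation: str,
    next_type: str,
    forward: bool,
    allowed: set[Node] | None = None,
) -> dict[Node, float]:
    """One propagation step: split each node's mass uniformly over its
    eligible neighbors (out-neighbors forward, in-neighbors backward),
    optionally restricted to an ``allowed`` set.  Mass at nodes with no
    eligible neighbor is dropped."""
    nxt: dict[Node, float] = {}
    for node, mass in masses.items():
        if forward:
            neighbors = graph.out_neighbors(node, relation, next_type)
        else:
            neighbors = graph.in_neighbors(node, relation, next_type)
        if allowed is not None:
            neighbors &= allowed
        if not neighbors:
            continue
        share = mass / len(neighbors)
        for neighbor in neighbors:
            nxt[neighbor] = nxt.get(neighbor, 0.0) + share
    return nxt


def propagate(
    graph: KnowledgeGraph,
    start: Node,
    half: Metapath,
    side: str,
    allowed_per_step: list[set[Node] | None] | None = None,
) -> ReachProfile:
    """Walk-probability profile for one half-metapath.

    On the left side the walk starts at ``start`` (which must carry the
    half's first type) and follows relations forward; on the right side it
    starts at the half's *last* type and follows relations backward, the
    mirror computation over in-neighbors.  ``allowed_per_step`` optionally
    restricts the nodes admissible at each subsequent step (used by pruned
    scoring).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    forward = side == "left"
    anchor_type = half.node_types[0] if forward else half.node_types[-1]
    if start.type != anchor_type:
        raise ValueError(
            f"start node type {start.type!r} does not match half-metapath "
            f"anchor type {anchor_type!r}"
        )
    if start not in graph.nodes:
        raise KeyError(f"unknown node {start}")

    masses: dict[Node, float] = {start: 1.0}
    steps = (
        list(zip(half.relations, half.node_types[1:]))
        if forward
        else list(zip(half.relations[::-1], half.node_types[-2::-1]))
    )
    for i, (relation, next_type) in enumerate(steps):
        allowed = allowed_per_step[i] if allowed_per_step is not None else None
        masses = _spread(graph, masses, relation, next_type, forward, allowed)
    return ReachProfile(masses, side, len(steps))


def _edge_expand(
    graph: KnowledgeGraph,
    masses: dict[Node, float],
    relation: str,
    other_type: str,
    forward: bool,
) -> dict[CentralEntity, float]:
    """Distribute node masses onto middle-relation edge instances (odd
    length): each node's mass splits uniformly over its edges of the middle
    relation, keyed by the (source, relation, target) edge triple."""
    out: dict[CentralEntity, float] = {}
    for node, mass in masses.items():
        if forward:
            partners = graph.out_neighbors(node, relation, other_type)
            edges = [(node, relation, p) for p in partners]
        else:
            partners = graph.in_neighbors(node, relation, other_type)
            edges = [(p, relation, node) for p in partners]
        if not edges:
            continue
        share = mass / len(edges)
        for edge in edges:
            out[edge] = out.get(edge, 0.0) + share
    return out


def left_profile(
    graph: KnowledgeGraph, s: Node, decomposition: MetapathSplit
) -> dict[CentralEntity, float]:
    """Central-entity reach profile from the source along the left half."""
    profile = propagate(graph, s, decomposition.left, "left")
    if decomposition.central_kind == "node-type":
        return dict(profile.masses)
    return _edge_expand(
        graph,
        profile.masses,
        decomposition.middle_relation,
        decomposition.right.node_types[0],
        forward=True,
    )


def right_profile(
    graph: KnowledgeGraph, t: Node, decomposition: MetapathSplit
) -> dict[CentralEntity, float]:
    """Central-entity reach profile from the target along the right half,
    walked backwards."""
    profile = propagate(graph, t, decomposition.right, "right")
    if decomposition.central_kind == "node-type":
        return dict(profile.masses)
    return _edge_expand(
        graph,
        profile.masses,
        decomposition.middle_relation,
        decomposition.left.node_types[-1],
        forward=False,
    )


def hetesim(
    graph: KnowledgeGraph, s: Node, t: Node, metapath: Metapath
) -> HeteSimScore:
    """HeteSim: cosine of the two half-walk reach profiles.

    Equals the normalized product of the relevant reachable-probability
    matrix rows; symmetric under swapping ``(s, P)`` with ``(t, reverse(P))``.
    """
    if s.type != metapath.source_type or t.type != metapath.target_type:
        raise ValueError(
            f"endpoint types ({s.type}, {t.type}) do not match metapath {metapath}"
        )
    decomposition = split(metapath)
    left = left_profile(graph, s, decomposition)
    right = right_profile(graph, t, decomposition)
    if not left or not right:
        return HeteSimScore(0.0, defined=False)
    return HeteSimScore(cosine(left, right), defined=True)
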