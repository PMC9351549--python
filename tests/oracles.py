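"""Independent brute-force oracles for small graphs.

Everything here recomputes quantities by exhaustive walk enumeration over a
networkx multigraph, deliberately sharing no code with the package's sparse
propagation, so that agreement is a genuine two-route check.  Exponential
in walk length; only ever applied to graphs of a few dozen nodes.
"""

from __future__ import annotations

import math
from fractions import Fraction

import networkx as nx

from hetesim import KnowledgeGraph, Metapath, Node


def to_networkx(graph: KnowledgeGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    g.add_nodes_from(graph.nodes)
    for source, label, target in graph.edges:
        g.add_edge(source, target, key=label)
    return g


def _step_neighbors(g: nx.MultiDiGraph, u: Node, relation: str, node_type: str,
                    forward: bool) -> list[Node]:
    if forward:
        return sorted(
            v for v in g.successors(u)
            if v.type == node_type and g.has_edge(u, v, key=relation)
        )
    return sorted(
        v for v in g.predecessors(u)
        if v.type == node_type and g.has_edge(v, u, key=relation)
    )


def enumerate_walks(g: nx.MultiDiGraph, start: Node, steps: list[tuple[str, str]],
                    forward: bool) -> list[tuple[tuple[Node, ...], Fraction]]:
    """All walks realizing the given (relation, next type) steps, with their
    uniform-random-walk probabilities; incomplete walks are dropped (their
    probability is the mass lost to dead ends)."""
    walks = [((start,), Fraction(1))]
    for relation, node_type in steps:
        extended = []
        for walk, prob in walks:
            neighbors = _step_neighbors(g, walk[-1], relation, node_type, forward)
            for v in neighbors:
                extended.append((walk + (v,), prob / len(neighbors)))
        walks = extended
    return walks


def _half_steps(metapath: Metapath) -> tuple[list, list, str]:
    """(left steps, reversed right steps, central kind); odd lengths append
    the middle relation as an extra step whose end nodes pair into edges."""
    l = metapath.length
    if l % 2 == 0:
        half = l // 2
        left = list(zip(metapath.relations[:half], metapath.node_types[1: half + 1]))
        right = list(zip(metapath.relations[half:][::-1],
                         metapath.node_types[half:-1][::-1]))
        return left, right, "node"
    mid = (l - 1) // 2
    left = list(zip(metapath.relations[: mid + 1], metapath.node_types[1: mid + 2]))
    right = list(zip(metapath.relations[mid:][::-1],
                     metapath.node_types[mid:-1][::-1]))
    return left, right, "edge"


def walk_profile(graph: KnowledgeGraph, anchor: Node, metapath: Metapath,
                 side: str) -> dict:
    """Central-entity probabilities by exhaustive walk enumeration."""
    g = to_networkx(graph)
    left_steps, right_steps, kind = _half_steps(metapath)
    steps = left_steps if side == "left" else right_steps
    masses: dict = {}
    for walk, prob in enumerate_walks(g, anchor, steps, forward=side == "left"):
        if kind == "node":
            key = walk[-1]
        else:
            u, v = walk[-2], walk[-1]
            mid_rel = steps[-1][0]
            key = (u, mid_rel, v) if side == "left" else (v, mid_rel, u)
        masses[key] = masses.get(key, Fraction(0)) + prob
    return masses


def brute_hetesim(graph: KnowledgeGraph, s: Node, t: Node,
                  metapath: Metapath) -> float:
    left = walk_profile(graph, s, metapath, "left")
    right = walk_profile(graph, t, metapath, "right")
    dot = sum(float(p) * float(right.get(k, 0)) for k, p in left.items())
    norm = math.sqrt(sum(float(p) ** 2 for p in left.values())) * math.sqrt(
        sum(float(p) ** 2 for p in right.values())
    )
    return dot / norm if norm else 0.0


def brute_dead_ends(graph: KnowledgeGraph, s: Node, t: Node,
                    metapath: Metapath) -> dict[int, set[Node]]:
    """Dead ends by definition: a node visited at step i by some half-walk
    prefix but by no *completed* half-walk.  Even-length metapaths only."""
    assert metapath.length % 2 == 0
    g = to_networkx(graph)
    l = metapath.length
    half = l // 2
    left_steps, right_steps, _ = _half_steps(metapath)
    per_step: dict[int, set[Node]] = {i: set() for i in range(1, l + 2)}

    for anchor, steps, positions, forward in (
        (s, left_steps, list(range(1, half + 2)), True),
        (t, right_steps, list(range(l + 1, half, -1)), False),
    ):
        visited: dict[int, set[Node]] = {p: set() for p in positions}
        completed: dict[int, set[Node]] = {p: set() for p in positions}
        prefixes = [(anchor,)]
        visited[positions[0]].add(anchor)
        for depth, (relation, node_type) in enumerate(steps):
            nxt = []
            for walk in prefixes:
                for v in _step_neighbors(g, walk[-1], relation, node_type, forward):
                    nxt.append(walk + (v,))
                    visited[positions[depth + 1]].add(v)
            prefixes = nxt
        for walk in prefixes:  # completed half-walks
            for depth, node in enumerate(walk):
                completed[positions[depth]].add(node)
        for depth, position in enumerate(positions[:-1]):  # central never dead
            per_step[position] |= visited[position] - completed[position]
    return {i: nodes for i, nodes in per_step.items() if nodes}


def brute_metapaths(graph: KnowledgeGraph, sources: set[Node], target: Node,
                    max_length: int) -> set[Metapath]:
    """Exhaustive walk enumeration, collecting the type signature of every
    walk of length <= max_length from a source to the target."""
    g = to_networkx(graph)
    found: set[Metapath] = set()
    stack = [((src,), (src.type,), ()) for src in sources]
    while stack:
        walk, types, relations = stack.pop()
        if len(relations) >= 1 and walk[-1] == target:
            found.add(Metapath(types, relations))
        if len(relations) == max_length:
            continue
        u = walk[-1]
        for v in g.successors(u):
            for relation in g.get_edge_data(u, v):
                stack.append(
                    (walk + (v,), types + (v.type,), relations + (relation,))
                )
    return found
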