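"""Synthetic knowledge-graph fixtures with known ground truth.

Three hand-specified families reconstruct classic worked examples of
HeteSim behavior, annotated with scores recomputed by the dense matrix
reference at build time (never stored stale):

* ``figure1_graph`` — the 10-node, 12-edge length-4 example whose left
  reach profile is (d: 1/3, e: 1/6, f: 1/6) and right profile
  (d: 1/4, e: 1/4, f: 1/2); node ``b`` is its single dead end.
* ``figure6_graph(m1, m2)`` — a length-4 family with m1-1 dead ends on the
  source side and m2-1 on the target side, all mass funneling through one
  shared central node, so the HeteSim score is exactly 1 for every m1, m2.
* ``figure7_graph(m)`` — a length-6 family where dead-end removal *does*
  change the score: m = 2 is dead-end-free with central profiles
  (3/4, 1/4) and (1/2, 1/2) and score 2/sqrt(5); for m >= 3 the extra m-2
  dead ends depress the plain score (5/sqrt(34) at m = 3, approaching
  sqrt(2)/2 as m grows) while the pruned score stays 2/sqrt(5).

``verification_graphs`` supplies three small layered graphs with
nontrivial dead-end structure (per-side reachable central counts <= 3) for
repeated-run validation of the randomized estimator, and
``make_random_hin`` generates seeded random layered networks guaranteed to
carry at least one full source-to-target instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hin import KnowledgeGraph, Node, Schema
from .metapath import Metapath
from .reference import hetesim_matrix

__all__ = [
    "FixtureSpec",
    "Fixture",
    "GenerationError",
    "figure1_graph",
    "figure6_graph",
    "figure7_graph",
    "verification_graphs",
    "make_random_hin",
    "make_fixture",
]


class GenerationError(RuntimeError):
    """Random generation could not satisfy its constraints."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters selecting one fixture family."""

    kind: str  # "fig1" | "fig6" | "fig7" | "layered-random"
    m1: int = 2
    m2: int = 2
    m: int = 2
    layer_sizes: tuple[int, ...] = (3, 4, 4, 3)
    edge_prob: float = 0.5
    dead_end_bias: float = 0.0
    seed: int | None = None


@dataclass(frozen=True)
class Fixture:
    """A generated graph plus its query and oracle-computed ground truth."""

    graph: KnowledgeGraph
    source: Node
    target: Node
    metapath: Metapath
    annotations: dict = field(default_factory=dict)


def _graph_from_edges(edges: Sequence[tuple[str, str, str, str, str]]) -> KnowledgeGraph:
    schema = Schema.from_relations(
        {(pred, s_type, o_type) for _, s_type, pred, _, o_type in edges}
    )
    graph = KnowledgeGraph(schema)
    for s_id, s_type, pred, o_id, o_type in edges:
        graph.add_edge(Node(s_id, s_type), pred, Node(o_id, o_type))
    return graph


def _annotate(graph: KnowledgeGraph, s: Node, t: Node, metapath: Metapath) -> dict:
    value, defined = hetesim_matrix(graph, s, t, metapath)
    return {"hetesim": value, "hetesim_defined": defined}


def figure1_graph() -> Fixture:
    """The 10-node worked example: one length-4 metapath joins s to t.

    Left of the central layer: s fans out to a, b, c; a feeds d and f, c
    feeds d and e, and b goes nowhere (the dead end).  Right: d and e feed
    g, f feeds h, and g, h both feed t.
    """
    edges = [
        ("s", "A1", "R1", "a", "A2"),
        ("s", "A1", "R1", "b", "A2"),
        ("s", "A1", "R1", "c", "A2"),
        ("a", "A2", "R2", "d", "A3"),
        ("a", "A2", "R2", "f", "A3"),
        ("c", "A2", "R2", "d", "A3"),
        ("c", "A2", "R2", "e", "A3"),
        ("d", "A3", "R3", "g", "A4"),
        ("e", "A3", "R3", "g", "A4"),
        ("f", "A3", "R3", "h", "A4"),
        ("g", "A4", "R4", "t", "A5"),
        ("h", "A4", "R4", "t", "A5"),
    ]
    graph = _graph_from_edges(edges)
    metapath = Metapath(("A1", "A2", "A3", "A4", "A5"), ("R1", "R2", "R3", "R4"))
    s, t = Node("s", "A1"), Node("t", "A5")
    annotations = _annotate(graph, s, t, metapath)
    annotations["left_profile"] = {"d": 1 / 3, "e": 1 / 6, "f": 1 / 6}
    annotations["right_profile"] = {"d": 1 / 4, "e": 1 / 4, "f": 1 / 2}
    return Fixture(graph, s, t, metapath, annotations)


def figure6_graph(m1: int = 2, m2: int = 2) -> Fixture:
    """Length-4 dead-end family whose score is 1 for every m1, m2 >= 1.

    s has m1 neighbors of which m1-1 are dead ends; the one live neighbor
    leads to the single central node c.  Mirrored on the target side with
    m2 neighbors and m2-1 dead ends.
    """
    if m1 < 1 or m2 < 1:
        raise ValueError("m1 and m2 must be >= 1")
    edges = [("s", "A1", "R1", "u1", "A2"), ("u1", "A2", "R2", "c", "A3")]
    edges += [("s", "A1", "R1", f"u{i}", "A2") for i in range(2, m1 + 1)]
    edges += [("c", "A3", "R3", "z1", "A4"), ("z1", "A4", "R4", "t", "A5")]
    edges += [(f"z{i}", "A4", "R4", "t", "A5") for i in range(2, m2 + 1)]
    graph = _graph_from_edges(edges)
    metapath = Metapath(("A1", "A2", "A3", "A4", "A5"), ("R1", "R2", "R3", "R4"))
    s, t = Node("s", "A1"), Node("t", "A5")
    return Fixture(graph, s, t, metapath, _annotate(graph, s, t, metapath))


def figure7_graph(m: int = 2) -> Fixture:
    """Length-6 family where pruning changes the score for m >= 3.

    The source fans to a1 (leading only to central c1) and a2, which splits
    its mass over q1 -> c1, q2 -> c2 and m-2 dead ends; the target side has
    two clean chains into c1 and c2.  Central profiles at m = 2:
    (3/4, 1/4) against (1/2, 1/2).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    edges = [
        ("s", "T1", "R1", "a1", "T2"),
        ("s", "T1", "R1", "a2", "T2"),
        ("a1", "T2", "R2", "p", "T3"),
        ("p", "T3", "R3", "c1", "T4"),
        ("a2", "T2", "R2", "q1", "T3"),
        ("a2", "T2", "R2", "q2", "T3"),
        ("q1", "T3", "R3", "c1", "T4"),
        ("q2", "T3", "R3", "c2", "T4"),
        ("c1", "T4", "R4", "r1", "T5"),
        ("c2", "T4", "R4", "r2", "T5"),
        ("r1", "T5", "R5", "b1", "T6"),
        ("r2", "T5", "R5", "b2", "T6"),
        ("b1", "T6", "R6", "t", "T7"),
        ("b2", "T6", "R6", "t", "T7"),
    ]
    edges += [("a2", "T2", "R2", f"d{i}", "T3") for i in range(3, m + 1)]
    graph = _graph_from_edges(edges)
    metapath = Metapath(
        ("T1", "T2", "T3", "T4", "T5", "T6", "T7"),
        ("R1", "R2", "R3", "R4", "R5", "R6"),
    )
    s, t = Node("s", "T1"), Node("t", "T7")
    return Fixture(graph, s, t, metapath, _annotate(graph, s, t, metapath))


def verification_graphs() -> list[Fixture]:
    """Three deterministic layered graphs with nontrivial dead-end structure
    for repeated-run validation of the randomized estimator.

    Per-side reachable central counts are at most 3.  Exact pruned scores
    (closed form): 2/sqrt(5), 2*sqrt(3)/sqrt(14), and 2/sqrt(5).
    """
    first = figure7_graph(4)

    # three central nodes, dead ends on both sides
    edges2 = [
        ("s", "T1", "R1", "a1", "T2"),
        ("s", "T1", "R1", "a2", "T2"),
        ("s", "T1", "R1", "a3", "T2"),
        ("a1", "T2", "R2", "p1", "T3"),
        ("p1", "T3", "R3", "c1", "T4"),
        ("a2", "T2", "R2", "q1", "T3"),
        ("a2", "T2", "R2", "q2", "T3"),
        ("a2", "T2", "R2", "dL1", "T3"),
        ("q1", "T3", "R3", "c1", "T4"),
        ("q2", "T3", "R3", "c2", "T4"),
        ("a3", "T2", "R2", "u1", "T3"),
        ("a3", "T2", "R2", "dL2", "T3"),
        ("u1", "T3", "R3", "c3", "T4"),
        ("c1", "T4", "R4", "r1", "T5"),
        ("c2", "T4", "R4", "r2", "T5"),
        ("c3", "T4", "R4", "r3", "T5"),
        ("r1", "T5", "R5", "b1", "T6"),
        ("r2", "T5", "R5", "b2", "T6"),
        ("dR1", "T5", "R5", "b2", "T6"),
        ("r3", "T5", "R5", "b3", "T6"),
        ("b1", "T6", "R6", "t", "T7"),
        ("b2", "T6", "R6", "t", "T7"),
        ("b3", "T6", "R6", "t", "T7"),
    ]
    metapath6 = Metapath(
        ("T1", "T2", "T3", "T4", "T5", "T6", "T7"),
        ("R1", "R2", "R3", "R4", "R5", "R6"),
    )
    graph2 = _graph_from_edges(edges2)
    s, t = Node("s", "T1"), Node("t", "T7")
    second = Fixture(graph2, s, t, metapath6, _annotate(graph2, s, t, metapath6))

    # cascading left dead end (a2 dies because everything below it does)
    edges3 = [
        ("s", "T1", "R1", "a1", "T2"),
        ("s", "T1", "R1", "a2", "T2"),
        ("a1", "T2", "R2", "p1", "T3"),
        ("a1", "T2", "R2", "p2", "T3"),
        ("a1", "T2", "R2", "p4", "T3"),
        ("p1", "T3", "R3", "c1", "T4"),
        ("p4", "T3", "R3", "c2", "T4"),
        ("a2", "T2", "R2", "p3", "T3"),
        ("c1", "T4", "R4", "r1", "T5"),
        ("c1", "T4", "R4", "r2", "T5"),
        ("c2", "T4", "R4", "r2", "T5"),
        ("r1", "T5", "R5", "b1", "T6"),
        ("r2", "T5", "R5", "b2", "T6"),
        ("b1", "T6", "R6", "t", "T7"),
        ("b2", "T6", "R6", "t", "T7"),
    ]
    graph3 = _graph_from_edges(edges3)
    third = Fixture(graph3, s, t, metapath6, _annotate(graph3, s, t, metapath6))
    return [first, second, third]


def make_random_hin(
    layers: Sequence[tuple[str, int]],
    edge_prob: float = 0.5,
    dead_end_bias: float = 0.0,
    seed: int | None = None,
    max_retries: int = 200,
) -> Fixture:
    """Seeded random layered network with >= 1 full source-target instance.

    Consecutive layers are joined by Bernoulli(edge_prob) edges over one
    relation per layer pair; ``dead_end_bias`` is the per-node probability
    of deleting all of a non-endpoint node's outgoing edges, seeding dead
    ends.  Resamples until a full instance survives.
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    if not 0.0 < edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in (0, 1]")
    if not 0.0 <= dead_end_bias < 1.0:
        raise ValueError("dead_end_bias must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    types = [t for t, _ in layers]
    if len(set(types)) != len(types):
        raise ValueError("layer types must be distinct")
    relations = [f"R{i + 1}" for i in range(len(layers) - 1)]
    metapath = Metapath(tuple(types), tuple(relations))

    for _ in range(max_retries):
        edges: list[tuple[str, str, str, str, str]] = []
        names = [
            [f"{t.lower()}{j}" for j in range(size)] for (t, size) in layers
        ]
        for i, relation in enumerate(relations):
            for u in names[i]:
                if i > 0 and rng.random() < dead_end_bias:
                    continue  # node keeps no outgoing edges: a dead-end seed
                picks = rng.random(len(names[i + 1])) < edge_prob
                for v, take in zip(names[i + 1], picks):
                    if take:
                        edges.append((u, types[i], relation, v, types[i + 1]))
        if not edges:
            continue
        graph = _graph_from_edges(edges)
        s = Node(names[0][0], types[0])
        t = Node(names[-1][0], types[-1])
        if not (graph.has_node(s) and graph.has_node(t)):
            continue
        value, defined = hetesim_matrix(graph, s, t, metapath)
        if defined:
            annotations = {"hetesim": value, "hetesim_defined": True}
            return Fixture(graph, s, t, metapath, annotations)
    raise GenerationError(
        f"no full instance after {max_retries} retries; "
        "raise edge_prob or lower dead_end_bias"
    )


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Dispatch on the fixture family described by ``spec``."""
    if spec.kind == "fig1":
        return figure1_graph()
    if spec.kind == "fig6":
        return figure6_graph(spec.m1, spec.m2)
    if spec.kind == "fig7":
        return figure7_graph(spec.m)
    if spec.kind == "layered-random":
        types = [f"L{i + 1}" for i in range(len(spec.layer_sizes))]
        return make_random_hin(
            list(zip(types, spec.layer_sizes)),
            edge_prob=spec.edge_prob,
            dead_end_bias=spec.dead_end_bias,
            seed=spec.seed,
        )
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
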