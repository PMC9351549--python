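"""Dense transition-matrix reference scorer.

Computes HeteSim literally from its matrix definition: the reachable
probability matrix of a half-metapath is the product of row-normalized
typed adjacency matrices, and the score is the cosine of the source's
left-half row with the target's reversed-right-half row.  Odd-length
metapaths are handled by explicitly materializing one bridge node per
middle-relation edge in a copy of the graph.

This is deliberately the *other* route to the same quantity as the sparse
propagation scorer — dense numpy matrices and graph mutation instead of
dictionary propagation and the implicit middle-edge construction — and is
used to cross-check it and to annotate generated fixtures with ground
truth.  It is quadratic in type sizes and meant for small graphs only.
"""

from __future__ import annotations

import numpy as np

from .hin import KnowledgeGraph, Node, Relation, Schema
from .metapath import Metapath

__all__ = ["hetesim_matrix", "materialize_middle_edges"]

_E_TYPE = "_E"
_RE, _RF = "_RE", "_RF"


def materialize_middle_edges(
    graph: KnowledgeGraph, metapath: Metapath
) -> tuple[KnowledgeGraph, Metapath]:
    """Explicitly insert a bridge node per middle-relation edge (odd length).

    Returns a rebuilt graph and the equivalent even-length metapath
    ``A1..Amid -[_RE]-> _E -[_RF]-> Amid+1..``; every bridge node has
    exactly one in- and one out-edge, so walk probabilities are unchanged.
    """
    l = metapath.length
    if l % 2 == 0:
        raise ValueError("only odd-length metapaths need materialization")
    mid = (l - 1) // 2
    mid_rel = metapath.relations[mid]
    a_type = metapath.node_types[mid]
    b_type = metapath.node_types[mid + 1]

    relations = set(graph.schema.relations) | {
        Relation(_RE, a_type, _E_TYPE),
        Relation(_RF, _E_TYPE, b_type),
    }
    schema = Schema(
        frozenset(graph.schema.node_types | {_E_TYPE}), frozenset(relations)
    )
    out = KnowledgeGraph(schema)
    for source, label, target in graph.edges:
        if label == mid_rel and source.type == a_type and target.type == b_type:
            bridge = Node(f"{source.id}|{label}|{target.id}", _E_TYPE)
            out.add_edge(source, _RE, bridge)
            out.add_edge(bridge, _RF, target)
        else:
            out.add_edge(source, label, target)
    transformed = Metapath(
        metapath.node_types[: mid + 1] + (_E_TYPE,) + metapath.node_types[mid + 1 :],
        metapath.relations[:mid] + (_RE, _RF) + metapath.relations[mid + 1 :],
    )
    return out, transformed


def _row_normalize(matrix: np.ndarray) -> np.ndarray:
    sums = matrix.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(sums > 0, matrix / sums, 0.0)
    return normalized


def _transition(
    graph: KnowledgeGraph,
    rows: list[Node],
    cols: list[Node],
    relation: str,
    reverse: bool,
) -> np.ndarray:
    """Row-normalized typed adjacency between two node lists; ``reverse``
    builds the transition of the inverse relation."""
    w = np.zeros((len(rows), len(cols)))
    col_index = {node: j for j, node in enumerate(cols)}
    for i, u in enumerate(rows):
        neighbors = (
            graph.in_neighbors(u, relation, cols[0].type if cols else "")
            if reverse
            else graph.out_neighbors(u, relation, cols[0].type if cols else "")
        )
        for v in neighbors:
            w[i, col_index[v]] = 1.0
    return _row_normalize(w)


def _half_row(
    graph: KnowledgeGraph,
    start: Node,
    node_types: tuple[str, ...],
    relations: tuple[str, ...],
    reverse: bool,
) -> tuple[np.ndarray, list[Node]]:
    """One row of the reachable probability matrix for a half-metapath.

    Forward: walk ``relations`` left to right from ``start``.  Reverse: walk
    them right to left against edge direction (the reversed right half).
    """
    if reverse:
        node_types = node_types[::-1]
        relations = relations[::-1]
    layers = [graph.nodes_of_type(t) for t in node_types]
    if start not in layers[0]:
        raise ValueError(f"start node {start} is not of type {node_types[0]}")
    row = np.zeros(len(layers[0]))
    row[layers[0].index(start)] = 1.0
    for step, relation in enumerate(relations):
        u = _transition(graph, layers[step], layers[step + 1], relation, reverse)
        row = row @ u
    return row, layers[-1]


def hetesim_matrix(
    graph: KnowledgeGraph, s: Node, t: Node, metapath: Metapath
) -> tuple[float, bool]:
    """HeteSim via the explicit matrix product; returns (value, defined)."""
    if metapath.length % 2 == 1:
        graph, metapath = materialize_middle_edges(graph, metapath)
    half = metapath.length // 2
    left_row, left_nodes = _half_row(
        graph, s, metapath.node_types[: half + 1], metapath.relations[:half], False
    )
    right_row, right_nodes = _half_row(
        graph, t, metapath.node_types[half:], metapath.relations[half:], True
    )
    assert left_nodes == right_nodes  # both are the sorted central type layer
    norm = np.linalg.norm(left_row) * np.linalg.norm(right_row)
    if norm == 0.0:
        return 0.0, False
    return float(np.clip(left_row @ right_row / norm, 0.0, 1.0)), True
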