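"""Aggregating per-metapath scores into a single source ranking.

The relatedness of a candidate source to the target is the arithmetic mean
of its HeteSim (or pruned HeteSim) scores over *all* metapaths enumerated
for the query; a source lacking an instance of some metapath contributes 0
for it.  The mean can be approximated by sampling metapaths uniformly with
replacement — the estimator is unbiased and a bounded-differences
(McDiarmid) argument gives the sample size

    m = ceil( 1/(2 eps^2) * ln(2 |S| |T| / (1 - r)) )

for simultaneous additive error eps across all source-target pairs with
success probability r.  A combined budget for "sampled metapaths, each
scored by randomized walks" splits the failure probability between the two
stages.

The module also contains the exact optimum of the ULARA rank-aggregation
objective, kept as a demonstrator: the optimum provably places all weight
on a single ranking function (a simplex vertex), which is why mean-score
aggregation replaces it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .exact import hetesim
from .hin import KnowledgeGraph, Node
from .metapath import Metapath
from .pruned import c_of_eps, pruned_hetesim_exact

__all__ = [
    "AggregateScores",
    "UlaraInstance",
    "mean_hetesim",
    "required_metapath_samples",
    "approximate_mean_hetesim",
    "theorem3_parameters",
    "rank_sources",
    "ulara_degenerate_weights",
    "ulara_objective",
]

_SCORERS: dict[str, Callable] = {
    "exact": lambda g, s, t, p: hetesim(g, s, t, p),
    "pruned-exact": lambda g, s, t, p: pruned_hetesim_exact(g, s, t, p),
}


@dataclass(frozen=True)
class AggregateScores:
    """Per-source mean scores over a metapath collection.

    ``mode`` records whether the mean is exact over all metapaths or over a
    uniform-with-replacement sample of ``m`` of them; ``undefined_counts``
    tallies, per source, the metapaths whose score was undefined (no shared
    reachable central entity) and therefore entered the mean as 0.
    """

    per_source: dict[Node, float]
    metapaths_used: tuple[Metapath, ...]
    mode: str  # "exact" | "sampled"
    m: int
    params: tuple[float, float] | None = None  # (epsilon, r) in sampled mode
    undefined_counts: dict[Node, int] = field(default_factory=dict)


def _score_one(
    graph: KnowledgeGraph, s: Node, t: Node, metapath: Metapath, scorer: str
) -> tuple[float, bool]:
    """Score one (source, metapath) pair; type-incompatible pairs score 0."""
    if s.type != metapath.source_type or t.type != metapath.target_type:
        return 0.0, False
    result = _SCORERS[scorer](graph, s, t, metapath)
    return result.value, not result.defined


def mean_hetesim(
    graph: KnowledgeGraph,
    sources: Iterable[Node],
    target: Node,
    metapaths: Sequence[Metapath],
    scorer: str = "exact",
) -> AggregateScores:
    """Exact per-source mean over every metapath in ``metapaths``.

    Sources without an instance of (or the wrong endpoint type for) a
    metapath contribute 0 for it, so the divisor is always the full
    collection size.
    """
    if not metapaths:
        raise ValueError("the metapath collection must be nonempty")
    if scorer not in _SCORERS:
        raise ValueError(f"unknown scorer {scorer!r}")
    per_source: dict[Node, float] = {}
    undefined: dict[Node, int] = {}
    for s in sorted(set(sources)):
        total, n_undefined = 0.0, 0
        for metapath in metapaths:
            value, was_undefined = _score_one(graph, s, target, metapath, scorer)
            total += value
            n_undefined += was_undefined
        per_source[s] = total / len(metapaths)
        undefined[s] = n_undefined
    return AggregateScores(
        per_source=per_source,
        metapaths_used=tuple(metapaths),
        mode="exact",
        m=len(metapaths),
        undefined_counts=undefined,
    )


def required_metapath_samples(
    epsilon: float, r_success: float, s_size: int, t_size: int = 1
) -> int:
    """Metapath sample size for the approximate mean:
    ceil(1/(2 eps^2) * ln(2 |S| |T| / (1 - r_success)))."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    if not 0.0 < r_success < 1.0:
        raise ValueError(f"r_success must lie in (0, 1), got {r_success}")
    if s_size < 1 or t_size < 1:
        raise ValueError("|S| and |T| must be >= 1")
    bound = math.log(2.0 * s_size * t_size / (1.0 - r_success)) / (2.0 * epsilon**2)
    return int(math.ceil(bound))


def approximate_mean_hetesim(
    graph: KnowledgeGraph,
    sources: Iterable[Node],
    target: Node,
    metapaths: Sequence[Metapath],
    epsilon: float = 0.1,
    r_success: float = 0.9,
    seed: int | None = None,
    scorer: str = "exact",
) -> AggregateScores:
    """Approximate per-source mean from a uniform metapath sample.

    Samples ``m`` metapaths with replacement (independence is what the
    bounded-differences guarantee needs); when ``m`` would reach the
    collection size the exact mean is returned instead.  The estimate is
    within ``epsilon`` of the exact mean simultaneously for every source
    with probability at least ``r_success``.
    """
    if not metapaths:
        raise ValueError("the metapath collection must be nonempty")
    source_list = sorted(set(sources))
    m = required_metapath_samples(epsilon, r_success, len(source_list), 1)
    if m >= len(metapaths):
        return mean_hetesim(graph, source_list, target, metapaths, scorer)
    rng = np.random.default_rng(seed)
    ordered = sorted(metapaths, key=str)
    sampled = [ordered[i] for i in rng.integers(0, len(ordered), size=m)]
    per_source: dict[Node, float] = {}
    undefined: dict[Node, int] = {}
    for s in source_list:
        total, n_undefined = 0.0, 0
        for metapath in sampled:
            value, was_undefined = _score_one(graph, s, target, metapath, scorer)
            total += value
            n_undefined += was_undefined
        per_source[s] = total / m
        undefined[s] = n_undefined
    return AggregateScores(
        per_source=per_source,
        metapaths_used=tuple(sampled),
        mode="sampled",
        m=m,
        params=(epsilon, r_success),
        undefined_counts=undefined,
    )


def theorem3_parameters(
    epsilon: float,
    r_success: float,
    s_size: int,
    t_size: int,
    k_max: int,
) -> tuple[int, float, Callable[[int], int]]:
    """Combined budget for the approximate mean of randomized pruned scores.

    The total failure probability ``r = 1 - r_success`` is split between
    metapath sampling and walk estimation:

        r1      = r * x / (x + eps^2),   x = 4 ln(2|S||T|/r) * k_max
        m       = ceil( 2/eps^2 * ln(2|S||T| / (r - r1)) )
        n(k)    = ceil( 4 c(eps/2) * k / eps^2 * ln(4 m |S||T| k_max / r1) )

    Returns ``(m, r1, n)`` with ``n`` a function of a metapath's reachable
    central count k.  Structurally ``r1 < r`` always; parameter
    combinations driving ``r - r1`` to zero within floating point raise.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    if not 0.0 < r_success < 1.0:
        raise ValueError(f"r_success must lie in (0, 1), got {r_success}")
    if s_size < 1 or t_size < 1 or k_max < 1:
        raise ValueError("|S|, |T| and k_max must be >= 1")
    r_fail = 1.0 - r_success
    x = 4.0 * math.log(2.0 * s_size * t_size / r_fail) * k_max
    r1 = r_fail * x / (x + epsilon**2)
    if not r_fail - r1 > 0.0:
        raise ValueError(
            "failure budget r - r1 underflowed to zero for these parameters; "
            "use a larger epsilon or failure probability"
        )
    m = int(math.ceil(2.0 / epsilon**2 * math.log(2.0 * s_size * t_size / (r_fail - r1))))
    log_term = math.log(4.0 * m * s_size * t_size * k_max / r1)
    half_constant = 4.0 * c_of_eps(epsilon / 2.0)

    def walks_for(k: int) -> int:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        return int(math.ceil(half_constant * k / epsilon**2 * log_term))

    return m, r1, walks_for


def rank_sources(scores: AggregateScores) -> list[tuple[Node, float, int]]:
    """Total-order ranking: descending score, ties ascending by (id, type).

    Ranks are 1-based positions in this strict order, so the output is
    invariant to the input ordering of sources.
    """
    if not scores.per_source:
        raise ValueError("no sources to rank")
    ordered = sorted(scores.per_source.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(node, value, rank) for rank, (node, value) in enumerate(ordered, start=1)]


# -- ULARA degeneracy demonstrator ----------------------------------------


@dataclass(frozen=True)
class UlaraInstance:
    """A rank-aggregation instance: N ranking functions over |X| items,
    ``rank_matrix[i, x]`` the rank item x receives from function i (single
    query, every function ranks every item)."""

    rank_matrix: np.ndarray

    def __post_init__(self) -> None:
        matrix = np.asarray(self.rank_matrix, dtype=float)
        if matrix.ndim != 2 or matrix.size == 0:
            raise ValueError("rank_matrix must be a nonempty 2-D array")
        object.__setattr__(self, "rank_matrix", matrix)

    @property
    def disagreements(self) -> np.ndarray:
        """a_i = sum_x (r_i(x) - mean_rank(x))^2, one entry per function."""
        mu = self.rank_matrix.mean(axis=0)
        return ((self.rank_matrix - mu) ** 2).sum(axis=1)


def ulara_objective(instance: UlaraInstance, weights: np.ndarray) -> float:
    """The ULARA objective sum_i w_i * a_i at a simplex point."""
    return float(np.dot(instance.disagreements, np.asarray(weights, dtype=float)))


def ulara_degenerate_weights(instance: UlaraInstance) -> np.ndarray:
    """The exact ULARA optimum: all weight on the ranking function(s) with
    minimal squared disagreement from the mean rank.

    With a unique minimizer the optimum is a simplex vertex — the objective
    is linear in the weights — so ULARA selects a single ranking function
    rather than aggregating; ties split the weight uniformly.
    """
    a = instance.disagreements
    minimum = a.min()
    winners = np.flatnonzero(np.isclose(a, minimum, rtol=0.0, atol=1e-12))
    weights = np.zeros(len(a))
    weights[winners] = 1.0 / len(winners)
    return weights
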