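"""Dead-end identification, pruned HeteSim, the walk-count bound and the
randomized estimator."""

import math

import numpy as np
import pytest
import sympy as sp

from hetesim import (
    Metapath,
    Node,
    WalkBudgetExceededError,
    c_of_eps,
    figure6_graph,
    figure7_graph,
    find_dead_ends,
    hetesim,
    make_random_hin,
    pruned_hetesim_exact,
    randomized_pruned_hetesim,
    required_walks,
    verification_graphs,
    verification_report,
)
from hetesim.pruned import _exact_profile, _plans
from oracles import brute_dead_ends


def _c_highprec(epsilon):
    """Independent arbitrary-precision evaluation of the closed form."""
    C = (5 + 4 * sp.sqrt(2)) / 4
    eps = sp.Rational(str(epsilon))
    root = C + sp.sqrt(C**2 + 2 * eps)
    return sp.N(2 * root**2 + eps * root, 30)


class TestDeadEnds:
    def test_worked_example_dead_end(self, fig1):
        index = find_dead_ends(fig1.graph, fig1.source, fig1.target, fig1.metapath)
        assert index.per_step[2] == {Node("b", "A2")}
        assert sum(len(v) for i, v in index.per_step.items() if i != 2) == 0
        assert index.central_set == {
            Node("d", "A3"), Node("e", "A3"), Node("f", "A3")
        }

    @pytest.mark.parametrize("m1,m2", [(1, 1), (2, 2), (4, 6), (5, 2)])
    def test_dead_end_family_counts(self, m1, m2):
        fixture = figure6_graph(m1, m2)
        index = find_dead_ends(
            fixture.graph, fixture.source, fixture.target, fixture.metapath
        )
        assert len(index.per_step.get(2, set())) == m1 - 1
        assert len(index.per_step.get(4, set())) == m2 - 1

    def test_complete_layered_graph_has_no_dead_ends(self):
        fixture = make_random_hin(
            [("A", 3), ("B", 3), ("C", 3), ("D", 3), ("E", 3)],
            edge_prob=1.0, seed=0,
        )
        index = find_dead_ends(
            fixture.graph, fixture.source, fixture.target, fixture.metapath
        )
        assert index.n_dead == 0

    def test_matches_exhaustive_walk_check(self, random_fixtures):
        """Per-step dead ends equal the brute-force characterization: visited
        at step i by some prefix, by no completed half-walk."""
        for fixture in random_fixtures:
            if fixture.metapath.length % 2 == 1:
                continue
            index = find_dead_ends(
                fixture.graph, fixture.source, fixture.target, fixture.metapath
            )
            expected = brute_dead_ends(
                fixture.graph, fixture.source, fixture.target, fixture.metapath
            )
            got = {i: nodes for i, nodes in index.per_step.items() if nodes}
            assert got == expected


class TestPrunedExact:
    def test_short_metapaths_equal_plain_hetesim(self, short_random_fixtures):
        """Pruning provably cannot change the score for lengths <= 4: the
        only dead ends sit adjacent to an endpoint and rescale the reach
        vectors uniformly."""
        for fixture in short_random_fixtures:
            g = fixture.graph
            for s in g.nodes_of_type(fixture.metapath.source_type):
                for t in g.nodes_of_type(fixture.metapath.target_type):
                    plain = hetesim(g, s, t, fixture.metapath)
                    pruned = pruned_hetesim_exact(g, s, t, fixture.metapath)
                    assert pruned.value == pytest.approx(plain.value, abs=1e-12)

    def test_two_branch_family_baseline(self):
        fixture = figure7_graph(2)
        score = pruned_hetesim_exact(
            fixture.graph, fixture.source, fixture.target, fixture.metapath
        )
        assert score.exact and score.n_walks_used == (0, 0)
        assert score.value == pytest.approx(2 / math.sqrt(5), abs=1e-12)

    @pytest.mark.parametrize("m", [3, 4, 6])
    def test_pruning_recovers_the_dead_end_free_member(self, m):
        """Removing the family's dead ends yields its m = 2 member, so the
        pruned score equals that member's plain score for every m."""
        baseline = figure7_graph(2)
        expected = hetesim(
            baseline.graph, baseline.source, baseline.target, baseline.metapath
        ).value
        fixture = figure7_graph(m)
        pruned = pruned_hetesim_exact(
            fixture.graph, fixture.source, fixture.target, fixture.metapath
        )
        plain = hetesim(
            fixture.graph, fixture.source, fixture.target, fixture.metapath
        )
        assert pruned.value == pytest.approx(expected, abs=1e-12)
        assert abs(plain.value - pruned.value) > 1e-3  # pruning matters here

    def test_pruned_profiles_sum_to_one(self, random_fixtures):
        for fixture in random_fixtures:
            left, right = _plans(
                fixture.graph, fixture.source, fixture.target, fixture.metapath
            )
            if not (left.central & right.central):
                continue
            assert math.fsum(_exact_profile(left).values()) == pytest.approx(
                1.0, abs=1e-12
            )
            assert math.fsum(_exact_profile(right).values()) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_empty_central_set_gives_undefined_zero(self):
        fixture = figure6_graph(2, 2)
        # score the live source against a target reachable only through a
        # different central branch: drop the bridge by using a fresh target
        path = Metapath(("A2", "A3", "A4"), ("R2", "R3"))
        score = pruned_hetesim_exact(
            fixture.graph, Node("u2", "A2"), Node("z1", "A4"), path
        )
        assert score.value == 0.0 and not score.defined


class TestWalkBound:
    def test_small_epsilon_limit(self):
        c_limit = 8 * ((5 + 4 * math.sqrt(2)) / 4) ** 2
        assert c_of_eps(1e-12) == pytest.approx(c_limit, rel=1e-6)

    def test_monotone_and_bounded_by_71(self):
        grid = np.linspace(1e-6, 1.0, 2001)
        values = [c_of_eps(float(e)) for e in grid]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert max(values) <= 71.0

    @pytest.mark.parametrize("epsilon", [0.05, 0.1, 0.5, 1.0])
    def test_closed_form_against_high_precision_evaluation(self, epsilon):
        assert c_of_eps(epsilon) == pytest.approx(
            float(_c_highprec(epsilon)), rel=1e-14
        )

    def test_domain_errors(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                c_of_eps(bad)

    def test_required_walks_smallest_k(self):
        bound = c_of_eps(0.1) / 0.01 * math.log(4 / 0.1)
        assert required_walks(0.1, 0.9, 1) == int(math.floor(bound)) + 1

    def test_required_walks_example(self):
        expected = sp.floor(
            _c_highprec(0.05) / sp.Rational(1, 400) * 3 * sp.log(240)
        ) + 1
        assert required_walks(0.05, 0.95, 3) == int(expected)

    def test_required_walks_monotonicity(self):
        for eps_lo, eps_hi in [(0.05, 0.1), (0.1, 0.5)]:
            for r in (0.5, 0.9):
                for k in (1, 3, 10):
                    assert required_walks(eps_hi, r, k) <= required_walks(eps_lo, r, k)
        for k in (1, 2, 5):
            assert required_walks(0.1, 0.9, k) <= required_walks(0.1, 0.9, k + 1)
            assert required_walks(0.1, 0.9, k) <= required_walks(0.1, 0.95, k)

    def test_parameter_domains(self):
        with pytest.raises(ValueError):
            required_walks(0.1, 1.0, 1)
        with pytest.raises(ValueError):
            required_walks(0.1, 0.9, 0)


class TestRandomized:
    def test_deterministic_under_seed(self):
        fixture = figure7_graph(3)
        first = randomized_pruned_hetesim(
            fixture.graph, fixture.source, fixture.target, fixture.metapath,
            epsilon=0.2, r=0.9, seed=42,
        )
        second = randomized_pruned_hetesim(
            fixture.graph, fixture.source, fixture.target, fixture.metapath,
            epsilon=0.2, r=0.9, seed=42,
        )
        assert first.value == second.value  # bitwise
        assert first.n_walks_used == second.n_walks_used

    def test_singleton_central_set_estimates_exactly_one(self):
        fixture = figure6_graph(3, 4)
        for seed in range(5):
            score = randomized_pruned_hetesim(
                fixture.graph, fixture.source, fixture.target, fixture.metapath,
                epsilon=0.3, r=0.8, seed=seed,
            )
            assert score.value == 1.0

    def test_estimates_concentrate_around_exact_value(self):
        fixture = figure7_graph(3)
        exact = pruned_hetesim_exact(
            fixture.graph, fixture.source, fixture.target, fixture.metapath
        ).value
        errors = [
            abs(
                randomized_pruned_hetesim(
                    fixture.graph, fixture.source, fixture.target, fixture.metapath,
                    epsilon=0.2, r=0.9, seed=seed,
                ).value
                - exact
            )
            for seed in range(30)
        ]
        assert max(errors) <= 0.2

    def test_frequency_vectors_are_unbiased(self):
        """Averaging many independent estimates converges on the exact
        pruned score (law of large numbers, loose tolerance)."""
        fixture = figure7_graph(4)
        exact = pruned_hetesim_exact(
            fixture.graph, fixture.source, fixture.target, fixture.metapath
        ).value
        estimates = [
            randomized_pruned_hetesim(
                fixture.graph, fixture.source, fixture.target, fixture.metapath,
                epsilon=0.3, r=0.8, seed=seed,
            ).value
            for seed in range(60)
        ]
        assert np.mean(estimates) == pytest.approx(exact, abs=0.02)

    def test_empty_central_set_returns_zero_without_walking(self):
        fixture = figure6_graph(2, 2)
        path = Metapath(("A2", "A3", "A4"), ("R2", "R3"))
        score = randomized_pruned_hetesim(
            fixture.graph, Node("u2", "A2"), Node("z1", "A4"), path, seed=0
        )
        assert score.value == 0.0 and not score.defined
        assert score.n_walks_used == (0, 0)

    def test_safety_cap_raises_before_walking(self):
        fixture = figure7_graph(3)
        with pytest.raises(WalkBudgetExceededError):
            randomized_pruned_hetesim(
                fixture.graph, fixture.source, fixture.target, fixture.metapath,
                epsilon=0.05, r=0.95, seed=0, safety_cap=10,
            )

    def test_verification_report_structure(self):
        cases = [
            (f.graph, f.source, f.target, f.metapath)
            for f in verification_graphs()[:1]
        ]
        report = verification_report(cases, epsilon=0.2, r=0.8, runs=5, seed=7)
        case = report["cases"][0]
        assert len(case["estimates"]) == 5 and len(case["seeds"]) == 5
        assert case["max_error"] == pytest.approx(
            max(abs(e - case["exact"]) for e in case["estimates"])
        )
        assert report["max_error"] >= case["max_error"] - 1e-15
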