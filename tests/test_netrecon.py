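"""PCSF: interactome filtering, prizes, objective, exact vs heuristic solvers."""

import math

import networkx as nx
import numpy as np
import pytest

from patchnet.netrecon import (
    Forest,
    PCSFParams,
    adjusted_prizes,
    assign_prizes,
    edge_cost,
    filter_interactome,
    merge_networks,
    pcsf_objective,
    solve_pcsf_exact,
    solve_pcsf_heuristic,
)
from patchnet.structmap import MutationRecord


def make_graph(edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, confidence=w)
    return g


def random_instance(seed, n_max=12):
    """A small random weighted graph with random prizes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    g = nx.gnp_random_graph(n, 0.45, seed=int(seed))
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    for a, b in g.edges:
        g.edges[a, b]["confidence"] = float(np.round(rng.uniform(0.4, 1.0), 3))
    prizes = {}
    for v in sorted(g.nodes):
        if rng.random() < 0.4:
            prizes[v] = float(rng.choice([0.5, 1.0, 1.5, 2.0]))
    params = PCSFParams(
        omega=float(rng.choice([0.5, 1.0, 2.0, 10.0])),
        depth=int(rng.integers(2, 7)),
        beta=float(rng.choice([1.0, 2.0, 10.0])),
    )
    mu = float(rng.choice([0.0, 0.01, 0.1]))
    return g, prizes, params, mu


# ---------------------------------------------------------------------------
# filtering and prizes


class TestFilterInteractome:
    def test_confidence_threshold_inclusive(self):
        g = make_graph([("A", "B", 0.39), ("B", "C", 0.40)])
        filtered = filter_interactome(g, PCSFParams())
        assert not filtered.has_edge("A", "B")
        assert filtered.has_edge("B", "C")

    def test_blocklisted_protein_removed_with_edges(self):
        g = make_graph([("UBC", "X", 0.9), ("X", "Y", 0.9)])
        filtered = filter_interactome(g, PCSFParams())
        assert "UBC" not in filtered
        assert filtered.has_edge("X", "Y")

    def test_identity_when_nothing_filtered(self):
        g = make_graph([("A", "B", 1.0), ("B", "C", 1.0)])
        params = PCSFParams(excluded_proteins=())
        filtered = filter_interactome(g, params)
        assert set(filtered.edges) == set(g.edges)


class TestAssignPrizes:
    def _mut(self, protein, driver, significant):
        return MutationRecord(
            "p1", protein, 1, "A", "V", "missense",
            is_driver=driver, is_significant=significant,
        )

    def test_significant_driver_scores_one(self):
        assert assign_prizes([self._mut("G1", True, True)]) == {"G1": 1.0}

    def test_nonsignificant_driver_scores_half(self):
        assert assign_prizes([self._mut("G1", True, False)]) == {"G1": 0.5}

    def test_contributions_add_per_protein(self):
        prizes = assign_prizes(
            [self._mut("G1", True, True), self._mut("G1", True, False)]
        )
        assert prizes == {"G1": 1.5}

    def test_non_drivers_ignored(self):
        assert assign_prizes([self._mut("G1", False, True)]) == {}


# ---------------------------------------------------------------------------
# objective


class TestObjective:
    def test_empty_forest_forfeits_all_prizes(self):
        g = make_graph([("A", "B", 0.9)])
        params = PCSFParams(omega=0.5, beta=1.0)
        obj = pcsf_objective(nx.Graph(), {"A": 1.0, "B": 1.0}, g, params, mu=0.0)
        assert obj == pytest.approx(2.0)

    def test_single_edge_forest(self):
        g = make_graph([("A", "B", 0.9)])
        params = PCSFParams(omega=0.5, beta=1.0)
        f = nx.Graph()
        f.add_edge("A", "B")
        obj = pcsf_objective(f, {"A": 1.0, "B": 1.0}, g, params, mu=0.0)
        assert obj == pytest.approx(0.1 + 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_term_by_term_recomputation(self, seed):
        g, prizes, params, mu = random_instance(seed)
        # arbitrary forest: a spanning tree of one component's subset
        nodes = sorted(g.nodes)[: max(2, len(g) // 2)]
        sub = g.subgraph(nodes)
        comp = max(nx.connected_components(sub), key=len) if len(sub) else set()
        f = nx.minimum_spanning_tree(sub.subgraph(comp)) if comp else nx.Graph()
        obj = pcsf_objective(f, prizes, g, params, mu)
        # independent term-by-term tally
        p_adj = {v: prizes.get(v, 0.0) - mu * g.degree(v) for v in g.nodes}
        expected = params.omega * (1 if len(f) else 0)
        for v in g.nodes:
            if v in f:
                if p_adj[v] < 0:
                    expected += params.beta * -p_adj[v]
            elif p_adj[v] > 0:
                expected += params.beta * p_adj[v]
        for a, b in f.edges:
            expected += 1.0 - g.edges[a, b]["confidence"]
        assert obj == pytest.approx(expected, abs=1e-9)

    def test_foreign_forest_rejected(self):
        g = make_graph([("A", "B", 0.9)])
        f = nx.Graph()
        f.add_edge("A", "Z")
        with pytest.raises(ValueError):
            pcsf_objective(f, {}, g, PCSFParams(), 0.0)


# ---------------------------------------------------------------------------
# exact solver


def enumerate_optimum(graph, prizes, params, mu):
    """Fully independent optimum: try every node subset / spanning forest."""
    import itertools

    best = math.inf
    nodes = sorted(graph.nodes)
    for r in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            forest = nx.Graph()
            forest.add_nodes_from(subset)
            feasible = True
            for comp in nx.connected_components(sub):
                csub = sub.subgraph(comp).copy()
                for a, b in csub.edges:
                    csub.edges[a, b]["weight"] = 1.0 - csub.edges[a, b]["confidence"]
                tree = nx.minimum_spanning_tree(csub, weight="weight")
                p_adj = {v: prizes.get(v, 0.0) - mu * graph.degree(v) for v in comp}
                root = min(comp, key=lambda v: (-p_adj[v], v))
                ecc = nx.single_source_shortest_path_length(tree, root)
                if max(ecc.values(), default=0) > params.depth:
                    feasible = False
                    break
                forest.add_edges_from(tree.edges)
            if feasible:
                best = min(best, pcsf_objective(forest, prizes, graph, params, mu))
    return best


class TestExactSolver:
    def test_high_tree_penalty_keeps_forest_empty(self):
        g = make_graph([("A", "B", 0.9)])
        params = PCSFParams(omega=10.0, beta=1.0)
        f = solve_pcsf_exact(g, {"A": 1.0, "B": 1.0}, params, mu=0.0)
        assert f.nodes == set()
        assert f.objective == pytest.approx(2.0)

    def test_low_tree_penalty_connects_terminals(self):
        g = make_graph([("A", "B", 0.9)])
        params = PCSFParams(omega=0.5, beta=1.0)
        f = solve_pcsf_exact(g, {"A": 1.0, "B": 1.0}, params, mu=0.0)
        assert f.nodes == {"A", "B"}
        assert f.edges == {frozenset(("A", "B"))}
        assert f.objective == pytest.approx(0.6)

    def test_large_hub_penalty_excludes_hub(self):
        # star: hub H connects terminals T1..T4
        g = make_graph(
            [("H", f"T{i}", 0.9) for i in range(1, 5)]
        )
        params = PCSFParams(omega=0.4, beta=1.0)
        f = solve_pcsf_exact(g, {f"T{i}": 1.0 for i in range(1, 5)}, params, mu=2.0)
        assert "H" not in f.nodes

    @pytest.mark.parametrize("seed", range(10))
    def test_attains_independent_enumeration_optimum(self, seed):
        g, prizes, params, mu = random_instance(seed, n_max=8)
        f = solve_pcsf_exact(g, prizes, params, mu)
        assert f.objective == pytest.approx(
            enumerate_optimum(g, prizes, params, mu), abs=1e-9
        )

    def test_size_guard(self):
        g = nx.path_graph(13)
        with pytest.raises(ValueError):
            solve_pcsf_exact(g, {}, PCSFParams(), 0.0)


class TestHeuristic:
    def test_no_positive_adjusted_prizes_empty_forest(self):
        g = make_graph([("A", "B", 0.9)])
        f = solve_pcsf_heuristic(g, {}, PCSFParams(), mu=0.0)
        assert f.nodes == set()

    def test_single_worthwhile_terminal_singleton_tree(self):
        g = make_graph([("A", "B", 0.9)])
        params = PCSFParams(omega=0.5, beta=1.0)
        f = solve_pcsf_heuristic(g, {"A": 1.0}, params, mu=0.0)
        assert f.nodes == {"A"}
        assert f.roles["A"] == "terminal"

    def test_break_even_seed_is_pruned(self):
        # beta * prize == omega: a lone terminal is not worth a tree
        g = make_graph([("A", "B", 0.9)])
        params = PCSFParams(omega=10.0, beta=10.0)
        f = solve_pcsf_heuristic(g, {"A": 1.0}, params, mu=0.0)
        assert f.nodes == set()

    @pytest.mark.parametrize("seed", range(30))
    def test_never_beats_exact_and_respects_constraints(self, seed):
        g, prizes, params, mu = random_instance(seed)
        exact = solve_pcsf_exact(g, prizes, params, mu)
        heur = solve_pcsf_heuristic(g, prizes, params, mu)
        assert heur.objective >= exact.objective - 1e-9
        # acyclic
        assert len(heur.graph) == 0 or nx.is_forest(heur.graph)
        # depth bound per component from its root
        p_adj = adjusted_prizes(g, prizes, mu)
        for comp in nx.connected_components(heur.graph):
            root = min(comp, key=lambda v: (-p_adj[v], v))
            ecc = nx.single_source_shortest_path_length(
                heur.graph.subgraph(comp), root
            )
            assert max(ecc.values(), default=0) <= params.depth

    def test_matches_exact_on_most_instances(self):
        hits = 0
        n = 40
        for seed in range(n):
            g, prizes, params, mu = random_instance(seed + 1000)
            exact = solve_pcsf_exact(g, prizes, params, mu)
            heur = solve_pcsf_heuristic(g, prizes, params, mu)
            if heur.objective <= exact.objective + 1e-9:
                hits += 1
        assert hits / n >= 0.8

    def test_omega_monotonicity_in_tree_count(self):
        for seed in range(6):
            g, prizes, _params, mu = random_instance(seed, n_max=8)
            trees = []
            for omega in (0.25, 1.0, 4.0):
                params = PCSFParams(omega=omega, depth=6, beta=2.0)
                trees.append(solve_pcsf_exact(g, prizes, params, mu).n_trees)
            assert trees == sorted(trees, reverse=True)


class TestMerge:
    def _forest(self, edges, roles):
        g = nx.Graph()
        g.add_edges_from(edges)
        return Forest(graph=g, roles=roles)

    def test_identical_forests(self):
        f = self._forest([("A", "B")], {"A": "terminal", "B": "steiner"})
        merged = merge_networks(f, f)
        assert set(merged.nodes) == {"A", "B"}
        assert merged.number_of_edges() == 1

    def test_disjoint_union(self):
        f1 = self._forest([("A", "B")], {"A": "terminal", "B": "steiner"})
        f2 = self._forest([("C", "D")], {"C": "terminal", "D": "steiner"})
        merged = merge_networks(f1, f2)
        assert set(merged.nodes) == {"A", "B", "C", "D"}

    def test_terminal_role_wins(self):
        f1 = self._forest([("A", "B")], {"A": "steiner", "B": "steiner"})
        f2 = self._forest([("A", "C")], {"A": "terminal", "C": "steiner"})
        merged = merge_networks(f1, f2)
        assert merged.nodes["A"]["role"] == "terminal"


class TestParams:
    def test_yaml_roundtrip(self):
        text = "omega: 5.0\ndepth: 4\nmus: [0.01]\nmin_confidence: 0.5\n"
        params = PCSFParams.from_yaml(text)
        assert params.omega == 5.0 and params.depth == 4
        assert params.mus == (0.01,)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PCSFParams(omega=-1)
        with pytest.raises(ValueError):
            PCSFParams(depth=0)

    def test_edge_cost_transforms(self):
        assert edge_cost(0.9, "linear") == pytest.approx(0.1)
        assert edge_cost(1.0, "neglog") == pytest.approx(0.0)
        with pytest.raises(ValueError):
            edge_cost(0.5, "quadratic")
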