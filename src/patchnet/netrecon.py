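"""Patient-specific subnetwork reconstruction by prize-collecting Steiner
forests (PCSF) on a confidence-weighted interactome.

Each patient's mutated driver proteins become prize-carrying terminals;
the solver selects a subforest of the interactome minimizing

    sum of forfeited scaled prizes  beta * p'(v)+   over excluded nodes
  + sum of edge costs               c(e) = 1 - confidence(e)
  + per-tree penalty                omega * (number of trees)

where p'(v) = p(v) - mu * deg(v) is the hub-adjusted prize (high-degree
proteins are discouraged from entering on prize alone) and including a node
with negative p' costs beta * |p'(v)|. Every tree must satisfy a depth bound
D measured in edges from the tree root (the highest-p' node of the tree).

Two solvers share this objective: an exhaustive exact solver for small
instances (the test oracle) and a deterministic greedy heuristic used at
cohort scale. Patient networks are produced by running the heuristic at two
hub-penalty settings and merging the resulting node/edge sets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .structmap import MutationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PCSFParams",
    "Forest",
    "DEFAULT_EXCLUDED_PROTEINS",
    "load_interactome",
    "write_interactome",
    "filter_interactome",
    "assign_prizes",
    "edge_cost",
    "pcsf_objective",
    "solve_pcsf_exact",
    "solve_pcsf_heuristic",
    "merge_networks",
    "reconstruct_patient_network",
]

#: Promiscuous / very large proteins removed before reconstruction to limit
#: noise from random hits: ubiquitous interactors plus giant ORFs whose
#: mutation counts scale with length rather than selection.
DEFAULT_EXCLUDED_PROTEINS: tuple[str, ...] = (
    "UBC", "APP", "ELAVL1", "SUMO2", "CUL3",
    "TTN", "MUC16", "SYNE1", "NEB", "MUC19", "CCDC168", "FSIP2", "OBSCN", "GPR98",
)


@dataclass
class PCSFParams:
    """PCSF tuning knobs.

    omega: per-tree penalty (controls forest fragmentation).
    depth: maximum edges from a tree's root to any of its leaves.
    beta: prize scale (pushes terminals into the network).
    mus: hub-penalty settings; one reconstruction per value, then merged.
    min_confidence: interactome edges below this confidence are discarded.
    excluded_proteins: removed from the interactome with all their edges.
    cost_transform: 'linear' (1 - w) or 'neglog' (-log w) edge costs.
    """

    omega: float = 10.0
    depth: int = 6
    beta: float = 10.0
    mus: tuple[float, ...] = (0.005, 0.01)
    min_confidence: float = 0.4
    excluded_proteins: tuple[str, ...] = DEFAULT_EXCLUDED_PROTEINS
    cost_transform: str = "linear"

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.beta <= 0:
            raise ValueError("omega and beta must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if any(mu < 0 for mu in self.mus):
            raise ValueError("mu must be non-negative")

    @classmethod
    def from_yaml(cls, text: str) -> "PCSFParams":
        data = yaml.safe_load(text) or {}
        if "mus" in data:
            data["mus"] = tuple(data["mus"])
        if "excluded_proteins" in data:
            data["excluded_proteins"] = tuple(data["excluded_proteins"])
        return cls(**data)


@dataclass
class Forest:
    """A PCSF solution: an acyclic subgraph of the interactome.

    ``roots`` maps each tree (component) to its root, the highest adjusted
    prize node; ``roles`` marks nodes terminal (prize > 0) or Steiner.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    roots: dict[str, str] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    objective: float = math.nan

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_trees(self) -> int:
        return nx.number_connected_components(self.graph) if len(self.graph) else 0


# ---------------------------------------------------------------------------
# interactome handling


def load_interactome(path_or_buffer) -> nx.Graph:
    """Read a TSV edge list (prot_a, prot_b, confidence) into a graph."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    graph = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        w = float(w)
        if not 0.0 < w <= 1.0:
            raise ValueError(f"confidence {w} for edge ({a}, {b}) outside (0, 1]")
        graph.add_edge(str(a), str(b), confidence=w)
    return graph


def write_interactome(graph: nx.Graph, path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), d["confidence"]) for a, b, d in graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["prot_a", "prot_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


def filter_interactome(raw: nx.Graph, params: PCSFParams | None = None) -> nx.Graph:
    """Drop low-confidence edges and blocklisted proteins; prune isolates."""
    params = params or PCSFParams()
    graph = nx.Graph()
    excluded = set(params.excluded_proteins)
    for a, b, data in raw.edges(data=True):
        if data["confidence"] < params.min_confidence:
            continue
        if a in excluded or b in excluded:
            continue
        graph.add_edge(a, b, **data)
    return graph


def assign_prizes(mutations: Sequence[MutationRecord]) -> dict[str, float]:
    """Per-protein terminal prizes from one patient's mutations.

    Each driver mutation contributes 1.0 when flagged significant and 0.5
    otherwise; contributions add over a protein's mutations, so recurrently
    mutated drivers carry proportionally larger prizes. Non-driver mutations
    contribute nothing.
    """
    prizes: dict[str, float] = {}
    for m in mutations:
        if not m.is_driver:
            continue
        prizes[m.protein] = prizes.get(m.protein, 0.0) + (1.0 if m.is_significant else 0.5)
    return prizes


def edge_cost(confidence: float, transform: str = "linear") -> float:
    if transform == "linear":
        return 1.0 - confidence
    if transform == "neglog":
        return -math.log(confidence)
    raise ValueError(f"unknown cost transform {transform!r}")


def _costs(graph: nx.Graph, transform: str) -> dict[frozenset[str], float]:
    return {
        frozenset((a, b)): edge_cost(d["confidence"], transform)
        for a, b, d in graph.edges(data=True)
    }


def adjusted_prizes(
    graph: nx.Graph, prizes: Mapping[str, float], mu: float
) -> dict[str, float]:
    """Hub-adjusted prizes p'(v) = p(v) - mu * degree(v) over graph nodes."""
    return {v: prizes.get(v, 0.0) - mu * graph.degree(v) for v in graph.nodes}


# ---------------------------------------------------------------------------
# objective


def pcsf_objective(
    forest: Forest | nx.Graph,
    prizes: Mapping[str, float],
    graph: nx.Graph,
    params: PCSFParams,
    mu: float,
) -> float:
    """Evaluate the PCSF objective of a candidate forest.

    Forfeited prizes are charged for every graph node with positive adjusted
    prize left out of the forest; included nodes with negative adjusted prize
    charge the magnitude of the deficit; edge costs and the per-tree penalty
    add on top.
    """
    fgraph = forest.graph if isinstance(forest, Forest) else forest
    for v in fgraph.nodes:
        if v not in graph:
            raise ValueError(f"forest node {v} not in interactome")
    for a, b in fgraph.edges:
        if not graph.has_edge(a, b):
            raise ValueError(f"forest edge ({a}, {b}) not in interactome")

    p_adj = adjusted_prizes(graph, prizes, mu)
    in_forest = set(fgraph.nodes)
    total = 0.0
    for v, p in p_adj.items():
        if v not in in_forest:
            total += params.beta * max(p, 0.0)
        elif p < 0:
            total += params.beta * (-p)
    for a, b in fgraph.edges:
        total += edge_cost(graph.edges[a, b]["confidence"], params.cost_transform)
    n_trees = nx.number_connected_components(fgraph) if len(fgraph) else 0
    total += params.omega * n_trees
    return total


def _component_root(nodes: set[str], p_adj: Mapping[str, float]) -> str:
    # highest adjusted prize; lexicographically smallest id on ties
    return min(nodes, key=lambda v: (-p_adj[v], v))


def _depth_ok(tree: nx.Graph, root: str, depth: int) -> bool:
    lengths = nx.single_source_shortest_path_length(tree, root, cutoff=depth + 1)
    if len(lengths) < len(tree):
        return False
    return max(lengths.values(), default=0) <= depth


def _finalize(
    fgraph: nx.Graph,
    prizes: Mapping[str, float],
    graph: nx.Graph,
    params: PCSFParams,
    mu: float,
) -> Forest:
    p_adj = adjusted_prizes(graph, prizes, mu)
    roots = {}
    for comp in nx.connected_components(fgraph):
        root = _component_root(comp, p_adj)
        roots[root] = root
    roles = {
        v: ("terminal" if prizes.get(v, 0.0) > 0 else "steiner") for v in fgraph.nodes
    }
    forest = Forest(fgraph, roots, roles)
    forest.objective = pcsf_objective(forest, prizes, graph, params, mu)
    return forest


# ---------------------------------------------------------------------------
# exact solver (test oracle for small instances)


MAX_EXACT_NODES = 12


def solve_pcsf_exact(
    graph: nx.Graph,
    prizes: Mapping[str, float],
    params: PCSFParams,
    mu: float = 0.0,
) -> Forest:
    """Globally optimal PCSF by exhaustive enumeration (tiny instances only).

    Enumerates every node subset; a subset is realised as the minimum
    spanning forest of its induced subgraph (one tree per induced component)
    and kept only when every tree satisfies the depth bound measured from its
    root, the highest adjusted-prize node. Ties in objective break toward
    fewer nodes, then the lexicographically smallest node set.
    """
    nodes = sorted(graph.nodes)
    if len(nodes) > MAX_EXACT_NODES:
        raise ValueError(
            f"exact solver limited to {MAX_EXACT_NODES} nodes, got {len(nodes)}"
        )
    p_adj = adjusted_prizes(graph, prizes, mu)
    costs = _costs(graph, params.cost_transform)

    best: tuple[float, int, tuple[str, ...]] | None = None
    best_graph: nx.Graph | None = None
    for r in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            msf = nx.Graph()
            msf.add_nodes_from(subset)
            for comp in nx.connected_components(sub):
                weighted = nx.Graph()
                weighted.add_nodes_from(comp)
                weighted.add_edges_from(
                    (a, b, {"weight": costs[frozenset((a, b))]})
                    for a, b in sub.subgraph(comp).edges
                )
                tree = nx.minimum_spanning_tree(weighted, weight="weight")
                root = _component_root(set(comp), p_adj)
                if not _depth_ok(tree, root, params.depth):
                    break
                msf.add_edges_from(tree.edges)
            else:
                obj = pcsf_objective(msf, prizes, graph, params, mu)
                key = (round(obj, 12), len(subset), subset)
                if best is None or key < best:
                    best = key
                    best_graph = msf
    assert best_graph is not None
    return _finalize(best_graph, prizes, graph, params, mu)


# ---------------------------------------------------------------------------
# greedy heuristic


def solve_pcsf_heuristic(
    graph: nx.Graph,
    prizes: Mapping[str, float],
    params: PCSFParams,
    mu: float = 0.0,
) -> Forest:
    """Deterministic greedy PCSF.

    The forest is seeded with the highest adjusted-prize terminal, then each
    step either attaches the terminal with the largest positive gain
    ``beta * p'(t) - dist_c(t, forest)`` along its cheapest path (edge costs
    plus inclusion penalties of new negative-p' interior nodes; path must
    keep the tree within the depth bound) or opens a new tree when
    ``beta * p'(t) - omega`` is the better positive option. Finally Steiner
    leaves, subtrees with non-positive net contribution and whole trees not
    worth their tree penalty are pruned — so a seeded tree that never became
    profitable is removed again. All ties break lexicographically by node id.
    """
    p_adj = adjusted_prizes(graph, prizes, mu)
    terminals = sorted(v for v in graph.nodes if prizes.get(v, 0.0) > 0)
    fgraph = nx.Graph()
    positive = [t for t in terminals if p_adj[t] > 0]
    if positive:
        seed = min(positive, key=lambda v: (-p_adj[v], v))
        fgraph.add_node(seed)

    def node_penalty(v: str) -> float:
        return params.beta * max(-p_adj[v], 0.0)

    def best_attachment(t: str) -> tuple[float, list[str]] | None:
        """Cheapest admissible path from the forest to terminal t."""
        if not len(fgraph):
            return None
        weight_cache: dict[tuple[str, str], float] = {}

        def weight(u, v, data):
            w = edge_cost(data["confidence"], params.cost_transform)
            if v not in fgraph:
                w += node_penalty(v) if v != t else 0.0
            return w

        best_path: tuple[float, list[str]] | None = None
        # multi-source Dijkstra from forest nodes toward t
        try:
            dist, paths = nx.multi_source_dijkstra(
                graph, set(fgraph.nodes), target=t, weight=weight
            )
        except nx.NetworkXNoPath:
            return None
        path = paths
        cost = dist + node_penalty(t)
        # depth check on the tentative component
        trial = fgraph.copy()
        nx.add_path(trial, path)
        comp = nx.node_connected_component(trial, t)
        root = _component_root(comp, p_adj)
        if not _depth_ok(trial.subgraph(comp), root, params.depth):
            return None
        if nx.cycle_basis(trial.subgraph(comp)):
            return None
        best_path = (cost, path)
        return best_path

    remaining = [t for t in terminals]
    while True:
        options: list[tuple[float, int, str, list[str] | None]] = []
        for t in remaining:
            if t in fgraph:
                continue
            attach = best_attachment(t)
            if attach is not None:
                cost, path = attach
                gain_attach = params.beta * p_adj[t] - cost
                if gain_attach > 0:
                    options.append((gain_attach, 0, t, path))
                    continue
            # no affordable path: open a new tree when worth the penalty
            gain_new = params.beta * p_adj[t] - params.omega
            if gain_new > 0:
                options.append((gain_new, 1, t, None))
        if not options:
            break
        # best gain; prefer attachment over a new tree on exact ties
        gain, kind, t, path = sorted(
            options, key=lambda o: (-o[0], o[1], o[2])
        )[0]
        if path is None:
            fgraph.add_node(t)
        else:
            nx.add_path(fgraph, path)
        remaining = [x for x in remaining if x not in fgraph]

    _prune(fgraph, graph, p_adj, params)
    fgraph = _local_improve(fgraph, graph, prizes, p_adj, params, mu)
    return _finalize(fgraph, prizes, graph, params, mu)


def _msf_on_subset(
    graph: nx.Graph,
    subset: set[str],
    costs: Mapping[frozenset[str], float],
    p_adj: Mapping[str, float],
    depth: int,
) -> nx.Graph | None:
    """Minimum spanning forest of the induced subgraph, or None when a tree
    would violate the depth bound from its root (highest adjusted prize)."""
    sub = graph.subgraph(subset)
    forest = nx.Graph()
    forest.add_nodes_from(subset)
    for comp in nx.connected_components(sub):
        weighted = nx.Graph()
        weighted.add_nodes_from(comp)
        weighted.add_edges_from(
            (a, b, {"weight": costs[frozenset((a, b))]})
            for a, b in sub.subgraph(comp).edges
        )
        tree = nx.minimum_spanning_tree(weighted, weight="weight")
        root = _component_root(set(comp), p_adj)
        if not _depth_ok(tree, root, depth):
            return None
        forest.add_edges_from(tree.edges)
    return forest


def _realize_subset(
    graph: nx.Graph,
    subset: set[str],
    costs: Mapping[frozenset[str], float],
    p_adj: Mapping[str, float],
    depth: int,
) -> nx.Graph:
    """Realize a node set as its depth-feasible minimum spanning forest.

    A forest is always the minimum spanning forest of its node set; when a
    tree of that forest breaks the depth bound, the node of smallest
    adjusted prize among those beyond the bound is dropped (ties break
    lexicographically) and the forest is rebuilt. This keeps both solvers
    in the same solution space: node subsets realized by their MSF.
    """
    subset = set(subset)
    while subset:
        forest = _msf_on_subset(graph, subset, costs, p_adj, depth)
        if forest is not None:
            return forest
        # locate nodes beyond the bound in the unconstrained MSF
        sub = graph.subgraph(subset)
        offenders: list[tuple[float, str]] = []
        for comp in nx.connected_components(sub):
            weighted = nx.Graph()
            weighted.add_nodes_from(comp)
            weighted.add_edges_from(
                (a, b, {"weight": costs[frozenset((a, b))]})
                for a, b in sub.subgraph(comp).edges
            )
            tree = nx.minimum_spanning_tree(weighted, weight="weight")
            root = _component_root(set(comp), p_adj)
            levels = nx.single_source_shortest_path_length(tree, root)
            offenders.extend(
                (p_adj[v], v) for v, lvl in levels.items() if lvl > depth
            )
        assert offenders, "depth violation without offending nodes"
        subset.discard(min(offenders, key=lambda o: (o[0], o[1]))[1])
    empty = nx.Graph()
    return empty


def _local_improve(
    fgraph: nx.Graph,
    graph: nx.Graph,
    prizes: Mapping[str, float],
    p_adj: Mapping[str, float],
    params: PCSFParams,
    mu: float,
) -> nx.Graph:
    """Deterministic post-pass: re-wire the selected nodes as their minimum
    spanning forest and greedily drop Steiner nodes while the objective
    improves. Greedy attachment paths are not always jointly optimal; this
    cleans up redundant connectors without touching terminals."""
    if not len(fgraph):
        return fgraph
    costs = _costs(graph, params.cost_transform)

    def score(candidate: nx.Graph) -> float:
        return pcsf_objective(candidate, prizes, graph, params, mu)

    current = _realize_subset(graph, set(fgraph.nodes), costs, p_adj, params.depth)
    improved = True
    while improved:
        improved = False
        best_obj = score(current)
        steiner = sorted(v for v in current.nodes if prizes.get(v, 0.0) <= 0)
        for v in steiner:
            candidate = _realize_subset(
                graph, set(current.nodes) - {v}, costs, p_adj, params.depth
            )
            obj = score(candidate)
            if obj < best_obj - 1e-12:
                current, best_obj, improved = candidate, obj, True
    return current


def _prune(
    fgraph: nx.Graph,
    graph: nx.Graph,
    p_adj: Mapping[str, float],
    params: PCSFParams,
) -> None:
    """Remove subtrees (and whole trees) whose net contribution is <= 0.

    The net value of a node is beta * p'(v) (prize saved if positive, hub
    penalty if negative); a subtree hanging off edge (parent, v) is dropped
    when its accumulated net value minus its internal and connecting edge
    costs is non-positive. A tree whose total net value does not cover the
    tree penalty omega is dropped entirely. Degree-1 Steiner nodes always
    fall out of this rule.
    """
    costs = _costs(graph, params.cost_transform)

    def subtree_net(tree: nx.Graph, v: str, parent: str | None) -> float:
        net = params.beta * p_adj[v]
        for child in list(tree[v]):
            if child == parent:
                continue
            child_net = subtree_net(tree, child, v) - costs[frozenset((v, child))]
            if child_net <= 0:
                doomed = set(
                    nx.dfs_preorder_nodes(_without_edge(tree, v, child), child)
                )
                tree.remove_nodes_from(doomed)
            else:
                net += child_net
        return net

    for comp in list(nx.connected_components(fgraph)):
        root = _component_root(comp, p_adj)
        tree = fgraph.subgraph(comp).copy()
        net = subtree_net(tree, root, None)
        if net - params.omega <= 0:
            fgraph.remove_nodes_from(comp)
        else:
            fgraph.remove_nodes_from(comp - set(tree.nodes))


def _without_edge(tree: nx.Graph, u: str, v: str) -> nx.Graph:
    g = tree.copy()
    g.remove_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# merging and patient-level driver


def merge_networks(*forests: Forest) -> nx.Graph:
    """Union of forest node and edge sets (terminal role wins over Steiner)."""
    merged = nx.Graph()
    roles: dict[str, str] = {}
    for f in forests:
        merged.add_nodes_from(f.graph.nodes)
        merged.add_edges_from(f.graph.edges)
        for v, role in f.roles.items():
            if roles.get(v) != "terminal":
                roles[v] = role
    nx.set_node_attributes(merged, roles, "role")
    return merged


def reconstruct_patient_network(
    interactome: nx.Graph,
    mutations: Sequence[MutationRecord],
    params: PCSFParams | None = None,
    prefiltered: bool = False,
) -> nx.Graph:
    """Full per-patient reconstruction: filter, prize, solve per mu, merge.

    Terminals absent from the filtered interactome are dropped with a log
    message. Returns the merged network (possibly empty).
    """
    params = params or PCSFParams()
    graph = interactome if prefiltered else filter_interactome(interactome, params)
    prizes = assign_prizes(mutations)
    missing = [p for p in prizes if p not in graph]
    if missing:
        logger.info("dropping %d terminals absent from interactome", len(missing))
    prizes = {p: v for p, v in prizes.items() if p in graph}
    if not prizes:
        return nx.Graph()
    forests = [
        solve_pcsf_heuristic(graph, prizes, params, mu) for mu in params.mus
    ]
    return merge_networks(*forests)


def write_forest(network: nx.Graph, edge_path, node_path, prizes=None) -> None:
    """SIF-style edge list plus a node attribute table."""
    edges = sorted((min(a, b), max(a, b)) for a, b in network.edges)
    pd.DataFrame(edges, columns=["prot_a", "prot_b"]).to_csv(
        edge_path, sep="\t", index=False
    )
    prizes = prizes or {}
    rows = [
        {
            "protein": v,
            "role": network.nodes[v].get("role", ""),
            "prize": prizes.get(v, 0.0),
            "degree": network.degree(v),
        }
        for v in sorted(network.nodes)
    ]
    pd.DataFrame(rows).to_csv(node_path, sep="\t", index=False)
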