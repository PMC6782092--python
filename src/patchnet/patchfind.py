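"""Residue contact graphs, 3D mutation patch detection and patch-based
patient grouping.

A *patch* is a set of mutated residues that are mutually reachable within two
residue-contact edges: two mutated residues belong together when they are
either in direct atomic contact (< 5 Å between any atom pair) or separated by
a single bridging residue. Mutated residues assigned to no patch are
*singletons*. Patches are detected cohort-wide, so a patch aggregates
mutations from many patients; a patch is *present* in a patient when the
patient carries at least one of its member mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.spatial import cKDTree

from .structmap import MutationRecord, RegionLabel, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "Patch",
    "PatientGroupAssignment",
    "build_contact_graph",
    "detect_patches",
    "classify_patch",
    "build_presence_matrix",
    "group_patients",
]

ResidueKey = tuple[str, str]


@dataclass
class Patch:
    """A detected spatial mutation cluster on one structure.

    ``members`` are the mutated residues (>= 2); ``bridges`` are non-mutated
    residues lying on a shortest length-2 contact path between two members.
    ``size`` counts mutated members only (the convention used for reported
    patch sizes); ``total_size`` additionally counts bridges. ``kind`` is
    ``intra`` when no member is interface-labelled and ``inter`` otherwise.
    """

    patch_id: str
    members: frozenset[ResidueKey]
    bridges: frozenset[ResidueKey]
    proteins: tuple[str, ...] = ()
    kind: str = ""
    mutations: list[MutationRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def total_size(self) -> int:
        return len(self.members | self.bridges)

    @property
    def patients(self) -> set[str]:
        return {m.patient for m in self.mutations}


@dataclass
class PatientGroupAssignment:
    """Ordered mutually exclusive patient groups plus the ungrouped remainder."""

    groups: list[tuple[str, str, set[str]]]  # (group id, defining feature, patients)
    ungrouped: set[str]

    def label_of(self) -> dict[str, str]:
        out = {p: gid for gid, _feat, members in self.groups for p in members}
        return out


# ---------------------------------------------------------------------------
# contact graph


def build_contact_graph(
    structure: Structure,
    cutoff: float = 5.0,
    include_sequence_neighbors: bool = True,
) -> nx.Graph:
    """Residue contact graph: an edge joins two residues whose closest atom
    pair lies strictly below ``cutoff`` Å.

    Covalently adjacent (sequence-neighbour) residues are almost always in
    atomic contact; ``include_sequence_neighbors=False`` removes those edges,
    which otherwise let patches grow along the backbone.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords, owners = structure.atom_table()
    graph = nx.Graph()
    order: dict[ResidueKey, int] = {}
    for idx, res in enumerate(structure.residues):
        graph.add_node(res.key)
        order[res.key] = idx

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff - 1e-12):
        u, v = owners[i], owners[j]
        if u == v:
            continue
        graph.add_edge(u, v)

    if not include_sequence_neighbors:
        seq_adjacent = []
        for u, v in graph.edges:
            ru, rv = structure.residues[order[u]], structure.residues[order[v]]
            if ru.chain_id == rv.chain_id and abs(order[u] - order[v]) == 1:
                seq_adjacent.append((u, v))
        graph.remove_edges_from(seq_adjacent)
    return graph


# ---------------------------------------------------------------------------
# patch detection


def detect_patches(
    graph: nx.Graph,
    mutated_residues: Iterable[ResidueKey],
    patch_prefix: str = "patch",
    proteins: tuple[str, ...] = (),
) -> tuple[list[Patch], set[ResidueKey]]:
    """Detect patches among mutated residues of one contact graph.

    An auxiliary graph on the mutated residues links two of them when their
    contact-graph distance is at most 2 edges; its connected components of
    size >= 2 are the patches and size-1 components the singletons. For every
    linked pair at distance exactly 2, every intermediate residue on every
    shortest path becomes a bridge residue of the patch. Mutated keys absent
    from the graph are logged and dropped.
    """
    mutated = set(mutated_residues)
    missing = mutated - set(graph.nodes)
    if missing:
        logger.info("dropping %d mutated keys absent from contact graph", len(missing))
        mutated -= missing

    aux = nx.Graph()
    aux.add_nodes_from(mutated)
    bridge_pool: dict[frozenset[ResidueKey], set[ResidueKey]] = {}
    for u in mutated:
        neigh_u = set(graph[u])
        for v in mutated:
            if v <= u:
                continue
            if v in neigh_u:
                aux.add_edge(u, v)
            else:
                between = neigh_u & set(graph[v])
                if between:
                    aux.add_edge(u, v)
                    bridge_pool[frozenset((u, v))] = between

    patches: list[Patch] = []
    singletons: set[ResidueKey] = set()
    components = sorted(nx.connected_components(aux), key=lambda c: sorted(c))
    idx = 1
    for comp in components:
        if len(comp) == 1:
            singletons |= comp
            continue
        bridges: set[ResidueKey] = set()
        for u, v in aux.subgraph(comp).edges:
            bridges |= bridge_pool.get(frozenset((u, v)), set())
        bridges -= comp
        patches.append(
            Patch(
                patch_id=f"{patch_prefix}-{idx}",
                members=frozenset(comp),
                bridges=frozenset(bridges),
                proteins=proteins,
            )
        )
        idx += 1
    return patches, singletons


def classify_patch(
    patch: Patch,
    region_labels: Mapping[ResidueKey, RegionLabel],
) -> str:
    """``inter`` iff at least one mutated member is interface-labelled, else
    ``intra``. Every member must carry a region label."""
    kinds = []
    for key in patch.members:
        label = region_labels.get(key)
        if label is None:
            raise ValueError(f"patch member {key} has no region label")
        kinds.append(label.label)
    return "inter" if any(k == "interface" for k in kinds) else "intra"


# ---------------------------------------------------------------------------
# presence matrix and grouping


def build_presence_matrix(
    features: Mapping[str, set[tuple[str, int]]],
    mutations: Sequence[MutationRecord],
) -> pd.DataFrame:
    """Boolean feature-by-patient presence matrix.

    ``features`` maps a feature id (patch or single mutation) to its member
    mutation sites as ``(protein, position)``. An entry is True iff the
    patient carries at least one mutation at a member site.
    """
    patients: list[str] = []
    seen = set()
    for m in mutations:
        if m.patient not in seen:
            seen.add(m.patient)
            patients.append(m.patient)
    by_patient: dict[str, set[tuple[str, int]]] = {p: set() for p in patients}
    for m in mutations:
        by_patient[m.patient].add((m.protein, m.position))

    data = {
        p: [bool(sites & by_patient[p]) for sites in features.values()]
        for p in patients
    }
    return pd.DataFrame(data, index=list(features), dtype=bool)


def group_patients(
    matrix: pd.DataFrame,
    min_group_size: int = 10,
) -> PatientGroupAssignment:
    """Iterative mutually exclusive grouping by feature frequency.

    The first group collects every patient carrying the most frequent
    feature; subsequent groups collect, among the remaining patients, the
    carriers of the feature most frequent *on the remainder*. Iteration stops
    when the best candidate group would fall below ``min_group_size``; the
    remaining patients are left ungrouped. Ties between equally frequent
    features break lexicographically by feature id.
    """
    remaining = list(matrix.columns)
    used_features: set[str] = set()
    groups: list[tuple[str, str, set[str]]] = []
    gid = 1
    while remaining:
        sub = matrix.loc[[f for f in matrix.index if f not in used_features], remaining]
        if sub.empty:
            break
        counts = sub.sum(axis=1)
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        feature, n_carriers = best
        if n_carriers < min_group_size:
            break
        members = {p for p in remaining if matrix.at[feature, p]}
        groups.append((f"group-{gid}", feature, members))
        used_features.add(feature)
        remaining = [p for p in remaining if p not in members]
        gid += 1
    return PatientGroupAssignment(groups, set(remaining))


# ---------------------------------------------------------------------------
# reporting


def patch_table(patches: Sequence[Patch]) -> pd.DataFrame:
    """Tabular patch summary (one row per patch)."""
    rows = []
    for p in patches:
        rows.append(
            {
                "patch_id": p.patch_id,
                "proteins": ";".join(p.proteins),
                "kind": p.kind,
                "size": p.size,
                "total_size": p.total_size,
                "members": ";".join(f"{c}:{r}" for c, r in sorted(p.members)),
                "bridges": ";".join(f"{c}:{r}" for c, r in sorted(p.bridges)),
                "n_patients": len(p.patients),
            }
        )
    return pd.DataFrame(rows)
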