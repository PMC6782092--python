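"""Linking patient groups to drug response through shared patch mutations.

A cell line is connected to a mutation patch when it carries at least one of
the patch's member mutations (same protein and position). Combining these
links with each group's signature patches, the lines' drug-response labels
and the drugs' target proteins yields a typed *therapeutic hypothesis
network*: group — signature patch — cell line — drug — target, where a
drug-target edge is kept only if the target protein actually appears in the
linked group's merged patient networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CellLineProfile",
    "link_patches_to_cell_lines",
    "classify_drug_response",
    "build_therapeutic_network",
]


@dataclass
class CellLineProfile:
    """Mutations, drug responses and drug targets of one cell line.

    ``responses`` maps drug id to either a label ('sensitive'/'resistant')
    or a z-score of log IC50 (negative = more sensitive than average).
    """

    line_id: str
    mutations: set[tuple[str, int]] = field(default_factory=set)  # (protein, position)
    responses: dict[str, str | float] = field(default_factory=dict)
    drug_targets: dict[str, set[str]] = field(default_factory=dict)


def link_patches_to_cell_lines(
    patch_sites: Mapping[str, set[tuple[str, int]]],
    lines: Sequence[CellLineProfile],
) -> pd.DataFrame:
    """Patch-to-cell-line edges via shared mutation sites.

    ``patch_sites`` maps patch id to its member mutation sites. An edge
    exists iff the line's mutation set intersects the patch's sites; the
    shared sites are recorded on the edge.
    """
    rows = []
    for line in lines:
        for patch_id, sites in patch_sites.items():
            shared = sites & line.mutations
            if shared:
                rows.append(
                    {
                        "patch": patch_id,
                        "cell_line": line.line_id,
                        "shared_mutations": ";".join(
                            f"{prot}:{pos}" for prot, pos in sorted(shared)
                        ),
                        "n_shared": len(shared),
                    }
                )
    return pd.DataFrame(rows, columns=["patch", "cell_line", "shared_mutations", "n_shared"])


def classify_drug_response(
    value: str | float | None,
    z_threshold: float = 1.0,
) -> str | None:
    """Binarize a drug response.

    Labels pass through unchanged; z-scores of log IC50 map to 'sensitive'
    at or below -threshold and 'resistant' at or above +threshold.
    Intermediate responses and missing values yield None (edge omitted).
    """
    if value is None:
        logger.info("missing drug response value; edge omitted")
        return None
    if isinstance(value, str):
        if value not in ("sensitive", "resistant"):
            raise ValueError(f"unknown response label {value!r}")
        return value
    z = float(value)
    if z <= -z_threshold:
        return "sensitive"
    if z >= z_threshold:
        return "resistant"
    return None


def build_therapeutic_network(
    signatures: pd.DataFrame,
    patch_line_edges: pd.DataFrame,
    lines: Sequence[CellLineProfile],
    group_networks: Mapping[str, set[str]],
    z_threshold: float = 1.0,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Assemble the group-patch-line-drug-target hypothesis network.

    ``signatures`` is the output of ``stratify.patch_group_enrichment``
    (rows with ``signature`` True define group-patch edges); ``group_networks``
    maps group id to the union protein set of its patients' merged networks.
    Drug-target edges survive only when the target is present in the linked
    group's network. Returns the typed graph and a flat hypotheses table
    ranked by (enrichment q ascending, |z| descending).
    """
    graph = nx.Graph()
    line_by_id = {l.line_id: l for l in lines}
    hypotheses = []

    sig_rows = signatures.loc[signatures["signature"]] if len(signatures) else signatures
    for _, sig in sig_rows.iterrows():
        group, patch, q = sig["group"], sig["patch"], sig["q"]
        graph.add_node(group, kind="group")
        graph.add_node(patch, kind="patch")
        graph.add_edge(group, patch, kind="signature", q=q)
        linked = (
            patch_line_edges.loc[patch_line_edges["patch"] == patch]
            if len(patch_line_edges)
            else patch_line_edges
        )
        for _, edge in linked.iterrows():
            line = line_by_id.get(edge["cell_line"])
            if line is None:
                continue
            graph.add_node(line.line_id, kind="cell_line")
            graph.add_edge(patch, line.line_id, kind="shared_mutation",
                           mutations=edge["shared_mutations"])
            for drug, value in sorted(line.responses.items()):
                label = classify_drug_response(value, z_threshold)
                if label is None:
                    continue
                graph.add_node(drug, kind="drug")
                graph.add_edge(line.line_id, drug, kind="response", label=label)
                z = float(value) if not isinstance(value, str) else float("nan")
                targets = line.drug_targets.get(drug, set())
                kept_targets = sorted(targets & group_networks.get(group, set()))
                for target in kept_targets:
                    graph.add_node(target, kind="target")
                    graph.add_edge(drug, target, kind="targets")
                hypotheses.append(
                    {
                        "group": group,
                        "patch": patch,
                        "cell_line": line.line_id,
                        "drug": drug,
                        "response": label,
                        "targets": ";".join(kept_targets),
                        "q": q,
                        "abs_z": abs(z) if z == z else float("nan"),
                    }
                )

    table = pd.DataFrame(
        hypotheses,
        columns=["group", "patch", "cell_line", "drug", "response", "targets", "q", "abs_z"],
    )
    if len(table):
        table = table.sort_values(
            ["q", "abs_z"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
    return graph, table


def write_therapeutic_network(graph: nx.Graph, path) -> None:
    """GraphML serialization of the typed hypothesis network."""
    nx.write_graphml(graph, path)
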