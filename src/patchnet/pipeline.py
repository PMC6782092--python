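"""End-to-end orchestration: cohort -> structural mapping -> patches ->
patient networks -> stratification -> therapeutic hypotheses.

This is the glue the individual analysis modules are designed around; each
step is also usable on its own. The driver works on a
:class:`~patchnet.synthcohort.SyntheticCohort` bundle, but only through the
same tables and structures a real study would supply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import druglink, netrecon, patchfind, stratify, structmap
from .synthcohort import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    structural_mutations: list[structmap.StructuralMutation]
    patches: list[patchfind.Patch]
    singletons: set[tuple[str, str]]
    patch_sites: dict[str, set[tuple[str, int]]]
    presence: pd.DataFrame
    patch_groups: patchfind.PatientGroupAssignment
    patch_group_logrank: tuple[float, int, float] | None
    patient_networks: dict[str, nx.Graph]
    es_matrix: pd.DataFrame
    cluster_labels: pd.Series
    consensus: pd.DataFrame
    cluster_logrank: tuple[float, int, float] | None
    signatures: pd.DataFrame
    patch_line_edges: pd.DataFrame
    hypotheses: pd.DataFrame
    therapeutic_network: nx.Graph = field(default_factory=nx.Graph)


def _survival_records(
    clinical: pd.DataFrame, groups: dict[str, str]
) -> list[stratify.SurvivalRecord]:
    records = []
    for row in clinical.itertuples(index=False):
        gid = groups.get(row.patient_id)
        if gid is None:
            continue
        records.append(
            stratify.SurvivalRecord(row.patient_id, float(row.days), int(row.event), gid)
        )
    return records


def _maybe_logrank(records: list[stratify.SurvivalRecord]):
    if len({r.group for r in records}) < 2:
        return None
    return stratify.logrank_test(records)


def run_pipeline(
    cohort: SyntheticCohort,
    pcsf_params: netrecon.PCSFParams | None = None,
    cluster_config: stratify.ClusterConfig | None = None,
    min_group_size: int = 10,
) -> PipelineResult:
    """Run the complete analysis on a cohort bundle."""
    config = cohort.config
    pcsf_params = pcsf_params or netrecon.PCSFParams()

    # --- structural mapping ----------------------------------------------
    mappings, regions = [], {}
    for protein, structure in sorted(cohort.structures.items()):
        seq, _keys = structmap.chain_sequence(structure, "A")
        mappings.append(
            structmap.align_sequence_to_structure(seq, structure, "A", protein=protein)
        )
        sasa = structmap.compute_sasa(structure, n_sphere_points=120)
        regions[protein] = structmap.classify_regions(structure, sasa)
    structural = structmap.map_mutations_to_structure(
        cohort.mutations, mappings, regions, cohort.structures
    )

    # --- patches ----------------------------------------------------------
    mutated_by_protein: dict[str, set[tuple[str, str]]] = {}
    sites_of_key: dict[tuple[str, tuple[str, str]], int] = {}
    for sm in structural:
        if sm.status != "mapped":
            continue
        structure_id, key, _label = sm.primary
        mutated_by_protein.setdefault(structure_id, set()).add(key)
        sites_of_key[(structure_id, key)] = sm.record.position

    patches: list[patchfind.Patch] = []
    singletons: set[tuple[str, str]] = set()
    for protein in sorted(mutated_by_protein):
        graph = patchfind.build_contact_graph(cohort.structures[protein])
        found, single = patchfind.detect_patches(
            graph, mutated_by_protein[protein],
            patch_prefix=protein, proteins=(protein,),
        )
        for p in found:
            p.kind = patchfind.classify_patch(p, regions[protein])
        patches.extend(found)
        singletons |= single

    patch_sites = {
        p.patch_id: {(p.proteins[0], sites_of_key[(p.proteins[0], k)]) for k in p.members}
        for p in patches
    }
    for p in patches:
        sites = patch_sites[p.patch_id]
        p.mutations = [
            m for m in cohort.mutations if (m.protein, m.position) in sites
        ]

    presence = patchfind.build_presence_matrix(patch_sites, cohort.mutations)
    patch_groups = patchfind.group_patients(presence, min_group_size=min_group_size)
    patch_group_records = _survival_records(cohort.clinical, patch_groups.label_of())
    patch_group_logrank = _maybe_logrank(patch_group_records)

    # --- patient networks -------------------------------------------------
    filtered = netrecon.filter_interactome(cohort.interactome, pcsf_params)
    by_patient: dict[str, list] = {}
    for m in cohort.mutations:
        by_patient.setdefault(m.patient, []).append(m)
    patient_networks = {
        patient: netrecon.reconstruct_patient_network(
            filtered, muts, pcsf_params, prefiltered=True
        )
        for patient, muts in sorted(by_patient.items())
    }

    # --- stratification ---------------------------------------------------
    universe = set(filtered.nodes)
    per_patient_ora = {
        patient: stratify.pathway_ora(net.nodes, cohort.pathways, universe)
        for patient, net in patient_networks.items()
        if len(net)
    }
    es = stratify.build_es_matrix(per_patient_ora)
    nonzero_cols = [c for c in es.columns if es[c].sum() > 0]
    es_clustered = es[nonzero_cols]
    n_groups = max(len(config.group_spec), 2)
    cluster_config = cluster_config or stratify.ClusterConfig(
        k=n_groups, n_iterations=50, seed=config.seed
    )
    labels, consensus = stratify.consensus_cluster(es_clustered, cluster_config)
    cluster_records = _survival_records(cohort.clinical, labels.to_dict())
    cluster_logrank = _maybe_logrank(cluster_records)
    signatures = stratify.patch_group_enrichment(presence, labels.to_dict())

    # --- drug linkage -----------------------------------------------------
    lines = _cell_line_profiles(cohort)
    patch_line_edges = druglink.link_patches_to_cell_lines(patch_sites, lines)
    group_networks: dict[str, set[str]] = {}
    for patient, gid in labels.items():
        group_networks.setdefault(gid, set()).update(patient_networks[patient].nodes)
    network, hypotheses = druglink.build_therapeutic_network(
        signatures, patch_line_edges, lines, group_networks
    )

    return PipelineResult(
        structural_mutations=structural,
        patches=patches,
        singletons=singletons,
        patch_sites=patch_sites,
        presence=presence,
        patch_groups=patch_groups,
        patch_group_logrank=patch_group_logrank,
        patient_networks=patient_networks,
        es_matrix=es,
        cluster_labels=labels,
        consensus=consensus,
        cluster_logrank=cluster_logrank,
        signatures=signatures,
        patch_line_edges=patch_line_edges,
        hypotheses=hypotheses,
        therapeutic_network=network,
    )


def _cell_line_profiles(cohort: SyntheticCohort) -> list[druglink.CellLineProfile]:
    targets = {
        row.drug: set([row.target]) for row in cohort.drug_targets.itertuples(index=False)
    }
    profiles: dict[str, druglink.CellLineProfile] = {}
    for row in cohort.cell_line_mutations.itertuples(index=False):
        prof = profiles.setdefault(
            row.cell_line, druglink.CellLineProfile(row.cell_line)
        )
        prof.mutations.add((str(row.protein), int(row.position)))
    for row in cohort.drug_response.itertuples(index=False):
        prof = profiles.setdefault(
            row.cell_line, druglink.CellLineProfile(row.cell_line)
        )
        prof.responses[row.drug] = row.response
        prof.drug_targets[row.drug] = targets.get(row.drug, set())
    return [profiles[k] for k in sorted(profiles)]
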