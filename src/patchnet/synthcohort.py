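"""Synthetic tumor-cohort generator with planted ground truth.

Emulates every input the pipeline consumes — compact toy protein folds,
patient mutation tables with spatially clustered ("planted patch") and
dispersed ("singleton") mutations, a confidence-weighted scale-free
interactome, pathway gene sets overlapping the planted driver proteins,
group-dependent survival times, and cell lines whose drug response depends
on planted patch membership — so that every downstream stage can be tested
end to end without external downloads.

The planted truth is unambiguous by construction: all members of a planted
patch are mutually within two contact-graph edges (they share a contact
hub), while singleton mutations are placed at graph distance greater than
two from every other mutated residue of the same protein.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import patchfind
from .structmap import (
    Atom,
    MutationRecord,
    ONE_TO_THREE,
    Residue,
    Structure,
    THREE_TO_ONE,
    compute_sasa,
    write_pdb,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedPatch",
    "GroupSpec",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticCohort",
    "GenerationError",
    "generate_structure",
    "plant_cohort",
    "generate_interactome",
    "generate_cell_lines",
    "generate_cohort",
    "write_mutation_table",
    "read_mutation_table",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class GenerationError(RuntimeError):
    """Raised when a configuration cannot be realised geometrically."""


@dataclass(frozen=True)
class PlantedPatch:
    """A spatial mutation cluster to plant: ``n_mutated`` residues of
    ``protein`` packed within ``spatial_radius`` Å around a contact hub."""

    protein: str
    n_mutated: int = 5
    spatial_radius: float = 12.0

    @property
    def label(self) -> str:
        return f"patch:{self.protein}"


@dataclass(frozen=True)
class GroupSpec:
    """A planted patient group: its signature patches and its exponential
    death hazard (events per day)."""

    group_id: str
    signature_patches: tuple[str, ...]   # planted patch labels
    hazard: float                        # per day


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale cohort: 60 patients in three survival
    groups, six structured driver proteins each carrying one planted patch
    of five mutated residues, two singleton mutations per patient, a
    150-protein scale-free interactome and 12 pathway sets.
    """

    n_patients: int = 60
    n_proteins: int = 150
    n_structures: int = 6
    residues_per_structure: int = 80
    planted_patches: tuple[PlantedPatch, ...] = tuple(
        PlantedPatch(f"G{i + 1}") for i in range(6)
    )
    singleton_rate: float = 2.0
    tsg_fraction: float = 0.3
    group_spec: tuple[GroupSpec, ...] = (
        GroupSpec("group-A", ("patch:G1", "patch:G2"), 1 / 150),
        GroupSpec("group-B", ("patch:G3", "patch:G4"), 1 / 300),
        GroupSpec("group-C", ("patch:G5", "patch:G6"), 1 / 600),
    )
    censoring_rate: float = 0.2
    interactome_degree_exponent: float = 2.5
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (10, 30)
    n_cell_lines: int = 20
    drug_effect_map: tuple[tuple[str, str, str], ...] = (
        ("drug-1", "patch:G1", "sensitive"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_patients, self.n_proteins, self.n_structures,
            self.residues_per_structure, self.n_pathways, self.n_cell_lines,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for rate in (self.tsg_fraction, self.censoring_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.singleton_rate < 0:
            raise ValueError("singleton_rate must be non-negative")
        for patch in self.planted_patches:
            if patch.n_mutated > self.residues_per_structure:
                raise ValueError(
                    f"planted patch on {patch.protein} larger than structure")
        labels = {p.label for p in self.planted_patches}
        for g in self.group_spec:
            unknown = set(g.signature_patches) - labels
            if unknown:
                raise ValueError(f"group {g.group_id} references unknown patches {unknown}")

    @property
    def structured_proteins(self) -> list[str]:
        """Proteins that get a structure (planted ones first)."""
        planted = []
        for p in self.planted_patches:
            if p.protein not in planted:
                planted.append(p.protein)
        extra = [f"G{i + 1}" for i in range(len(planted), self.n_structures)]
        return (planted + extra)[: max(self.n_structures, len(planted))]


@dataclass
class GroundTruth:
    """What was planted, for round-trip validation.

    ``patch_members`` maps a planted patch label to its member sites
    ``(protein, sequence position)``; ``singletons`` holds all singleton
    sites. Every planted mutated site appears in exactly one of the two.
    """

    patch_members: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    singletons: set[tuple[str, int]] = field(default_factory=set)
    patient_group: dict[str, str] = field(default_factory=dict)
    protein_role: dict[str, str] = field(default_factory=dict)
    cell_line_patches: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "patch_members": {
                    k: sorted(map(list, v)) for k, v in sorted(self.patch_members.items())
                },
                "singletons": sorted(map(list, self.singletons)),
                "patient_group": dict(sorted(self.patient_group.items())),
                "protein_role": dict(sorted(self.protein_role.items())),
                "cell_line_patches": {
                    k: sorted(v) for k, v in sorted(self.cell_line_patches.items())
                },
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# structures


def generate_structure(
    n_residues: int, seed: int, protein: str = "synthetic"
) -> Structure:
    """A compact single-chain toy fold.

    Backbone reference atoms follow a self-avoiding random walk with 3.8 Å
    steps (the CA-CA virtual bond length); candidate steps that reduce the
    radius of gyration are preferred with probability 0.7, producing a
    collapsed, contact-rich globule. Non-consecutive reference atoms keep at
    least 2.0 Å separation. Each residue also carries one pseudo side-chain
    atom. Residue types are drawn uniformly over the 20 amino acids.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    rng = np.random.default_rng(seed)
    step = 3.8
    # self-avoidance for non-consecutive reference atoms; 3.6 Å mimics the
    # packing of real CA traces (and comfortably clears the 2.0 Å floor)
    clash = 3.6
    coords = [np.zeros(3)]

    def random_units(k: int) -> np.ndarray:
        v = rng.normal(size=(k, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    attempts = 0
    while len(coords) < n_residues:
        candidates = coords[-1] + step * random_units(24)
        prev = np.asarray(coords)
        feasible = []
        for cand in candidates:
            d = np.linalg.norm(prev[:-1] - cand, axis=1) if len(prev) > 1 else np.array([clash + 1])
            if (d >= clash).all():
                feasible.append(cand)
        if not feasible:
            attempts += 1
            if attempts > 50:
                # restart the walk; rare for reasonable sizes
                coords = [np.zeros(3)]
                attempts = 0
            else:
                coords.pop() if len(coords) > 1 else None
            continue
        feasible_arr = np.asarray(feasible)
        rg = np.array([
            np.square(np.vstack([prev, c]) - np.vstack([prev, c]).mean(axis=0)).sum()
            for c in feasible_arr
        ])
        current_rg = np.square(prev - prev.mean(axis=0)).sum() * len(rg) / max(len(prev), 1)
        reducing = np.flatnonzero(rg <= np.median(rg))
        if rng.random() < 0.7 and len(reducing):
            pick = int(reducing[rng.integers(len(reducing))])
        else:
            pick = int(rng.integers(len(feasible_arr)))
        coords.append(feasible_arr[pick])
        _ = current_rg

    coords_arr = np.asarray(coords)
    centroid = coords_arr.mean(axis=0)
    residues = []
    for i, ca in enumerate(coords_arr):
        away = ca - centroid
        norm = np.linalg.norm(away)
        direction = away / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        cb = ca + 1.5 * direction
        resname = ONE_TO_THREE[AA_ALPHABET[int(rng.integers(20))]]
        residues.append(
            Residue(
                "A",
                str(i + 1),
                resname,
                (
                    Atom("CA", "C", tuple(np.round(ca, 3))),
                    Atom("CB", "C", tuple(np.round(cb, 3))),
                ),
            )
        )
    return Structure(protein, residues)


# ---------------------------------------------------------------------------
# cohort planting


def _surface_positions(structure: Structure) -> list[int]:
    """Positions with relative accessibility >= 5% (toy folds are open, so
    this keeps most residues; buried hub centres drop out)."""
    sasa = compute_sasa(structure, n_sphere_points=120)
    from .structmap import MAX_ASA_TIEN_2013

    out = []
    for res in structure.residues:
        if sasa[res.key] / MAX_ASA_TIEN_2013[res.resname] >= 0.05:
            out.append(int(res.resseq))
    return out or [int(r.resseq) for r in structure.residues]


def _plant_patch_sites(
    patch: PlantedPatch,
    structure: Structure,
    graph: nx.Graph,
    occupied: set[int],
    rng: np.random.Generator,
) -> set[int]:
    """Choose patch member positions: a contact hub plus neighbours within
    the spatial radius, all pairwise within two contact edges, and at graph
    distance > 2 from previously planted sites of the same protein."""
    pos_of = {key: int(key[1]) for key in graph.nodes}
    coords = {int(r.resseq): r.coords.mean(axis=0) for r in structure.residues}

    def far_from_occupied(candidates: set[int]) -> bool:
        if not occupied:
            return True
        occ_keys = [("A", str(p)) for p in occupied]
        for c in candidates:
            lengths = nx.single_source_shortest_path_length(graph, ("A", str(c)), cutoff=2)
            if any(k in lengths for k in occ_keys):
                return False
        return True

    hubs = sorted(graph.nodes, key=lambda v: (-graph.degree(v), pos_of[v]))
    order = rng.permutation(len(hubs))
    ranked = sorted(
        (hubs[i] for i in order),
        key=lambda v: -graph.degree(v),
    )
    for hub in ranked:
        center_pos = pos_of[hub]
        neigh = [
            pos_of[v]
            for v in graph[hub]
            if np.linalg.norm(coords[pos_of[v]] - coords[center_pos]) <= patch.spatial_radius
        ]
        if len(neigh) < patch.n_mutated - 1:
            continue
        chosen = set(
            int(x) for x in rng.choice(sorted(neigh), size=patch.n_mutated - 1, replace=False)
        ) | {center_pos}
        if far_from_occupied(chosen):
            return chosen
    raise GenerationError(
        f"cannot fit {patch.n_mutated} mutated residues within "
        f"{patch.spatial_radius} Å on {patch.protein}"
    )


def plant_cohort(
    config: SyntheticConfig,
    structures: Mapping[str, Structure],
) -> tuple[list[MutationRecord], pd.DataFrame, GroundTruth]:
    """Plant mutations, assign patients to groups and draw survival times.

    Every planted patch member site is mutated in at least one patient;
    patients of a group carry at least one mutation in each of the group's
    signature patches. Singleton mutations land on surface positions at
    contact-graph distance > 2 from every other mutated residue of the same
    protein. Survival times are exponential with the group hazard; a
    ``censoring_rate`` fraction of patients is censored uniformly before
    the drawn death time.
    """
    for patch in config.planted_patches:
        if patch.protein not in structures:
            raise ValueError(f"no structure for planted-patch protein {patch.protein}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = GroundTruth()

    graphs = {p: patchfind.build_contact_graph(s) for p, s in structures.items()}
    occupied: dict[str, set[int]] = {p: set() for p in structures}
    for patch in config.planted_patches:
        sites = _plant_patch_sites(
            patch, structures[patch.protein], graphs[patch.protein],
            occupied[patch.protein], rng,
        )
        occupied[patch.protein] |= sites
        truth.patch_members[patch.label] = {(patch.protein, s) for s in sites}

    # protein roles
    all_proteins = [f"G{i + 1}" for i in range(config.n_structures)] + [
        f"P{i + 1:03d}" for i in range(config.n_proteins - config.n_structures)
    ]
    n_tsg = int(round(config.tsg_fraction * len(all_proteins)))
    tsg_idx = set(rng.choice(len(all_proteins), size=n_tsg, replace=False).tolist())
    truth.protein_role = {
        p: ("tsg" if i in tsg_idx else "oncogene") for i, p in enumerate(all_proteins)
    }

    patients = [f"PT{i + 1:03d}" for i in range(config.n_patients)]
    groups = config.group_spec
    for i, patient in enumerate(patients):
        gid = groups[i % len(groups)].group_id if groups else ""
        truth.patient_group[patient] = gid

    def ref_aa(protein: str, pos: int) -> str:
        return THREE_TO_ONE[structures[protein].residue(("A", str(pos))).resname]

    def random_alt(ref: str) -> str:
        choices = [a for a in AA_ALPHABET if a != ref]
        return choices[int(rng.integers(len(choices)))]

    mutations: list[MutationRecord] = []

    def add_patch_mutation(patient: str, protein: str, pos: int) -> None:
        r = ref_aa(protein, pos)
        mutations.append(
            MutationRecord(
                patient=patient, protein=protein, position=pos,
                ref_aa=r, alt_aa=random_alt(r), mutation_type="missense",
                is_driver=True, is_significant=True,
                gene_role=truth.protein_role[protein],
            )
        )

    # signature patch mutations per patient
    by_group = {g.group_id: g for g in groups}
    carriers: dict[str, list[str]] = {p.label: [] for p in config.planted_patches}
    for patient in patients:
        gid = truth.patient_group[patient]
        if not gid:
            continue
        for label in by_group[gid].signature_patches:
            carriers[label].append(patient)

    # patches outside every signature still need carriers
    for patch in config.planted_patches:
        if not carriers[patch.label]:
            k = max(2, config.n_patients // 5)
            idx = rng.choice(config.n_patients, size=min(k, config.n_patients), replace=False)
            carriers[patch.label] = [patients[i] for i in sorted(idx)]

    for patch in config.planted_patches:
        sites = sorted(truth.patch_members[patch.label])
        pool = carriers[patch.label]
        seen_sites: set[tuple[str, int]] = set()
        for patient in pool:
            site = sites[int(rng.integers(len(sites)))]
            add_patch_mutation(patient, site[0], site[1])
            seen_sites.add(site)
        for site in sites:
            if site not in seen_sites:
                patient = pool[int(rng.integers(len(pool)))]
                add_patch_mutation(patient, site[0], site[1])

    # singleton mutations, kept > 2 contact edges from all other mutations
    surface = {p: _surface_positions(s) for p, s in structures.items()}
    mutated_by_protein: dict[str, set[int]] = {p: set(occ) for p, occ in occupied.items()}
    struct_proteins = list(structures)
    for patient in patients:
        n_single = int(rng.poisson(config.singleton_rate))
        for _ in range(n_single):
            protein = struct_proteins[int(rng.integers(len(struct_proteins)))]
            graph = graphs[protein]
            taken = mutated_by_protein[protein]
            candidates = []
            for pos in surface[protein]:
                if pos in taken:
                    continue
                lengths = nx.single_source_shortest_path_length(
                    graph, ("A", str(pos)), cutoff=2
                )
                if not any(("A", str(t)) in lengths for t in taken):
                    candidates.append(pos)
            if not candidates:
                logger.info("no singleton slot left on %s", protein)
                continue
            pos = candidates[int(rng.integers(len(candidates)))]
            mutated_by_protein[protein].add(pos)
            truth.singletons.add((protein, pos))
            r = ref_aa(protein, pos)
            nonsense = rng.random() < 0.1
            mutations.append(
                MutationRecord(
                    patient=patient, protein=protein, position=pos,
                    ref_aa=r,
                    alt_aa="*" if nonsense else random_alt(r),
                    mutation_type="nonsense" if nonsense else "missense",
                    is_driver=False, is_significant=False,
                    gene_role=truth.protein_role[protein],
                )
            )

    # survival
    rows = []
    for patient in patients:
        gid = truth.patient_group[patient]
        hazard = by_group[gid].hazard if gid else 1 / 365
        t_death = float(rng.exponential(1.0 / hazard))
        if rng.random() < config.censoring_rate:
            time, event = float(rng.uniform(0, t_death)), 0
        else:
            time, event = t_death, 1
        rows.append({"patient_id": patient, "days": round(time, 1), "event": event})
    clinical = pd.DataFrame(rows)

    mutations.sort(key=lambda m: (m.patient, m.protein, m.position, m.alt_aa))
    return mutations, clinical, truth


# ---------------------------------------------------------------------------
# interactome and pathways


def generate_interactome(
    config: SyntheticConfig,
    truth: GroundTruth | None = None,
) -> tuple[nx.Graph, dict[str, set[str]]]:
    """A connected, confidence-weighted scale-free interactome plus pathway
    gene sets.

    Degrees follow a power law with the configured exponent (Chung-Lu
    wiring); group signature proteins are additionally wired into small
    high-confidence modules with dedicated partner proteins, and each group
    gets a pathway covering its module, so that reconstructed patient
    networks carry a recoverable pathway signature. A few decoy pathways
    with disease-like names exercise the blocklist.
    """
    if config.n_proteins < 10:
        raise ValueError("need at least 10 proteins")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    proteins = [f"G{i + 1}" for i in range(config.n_structures)] + [
        f"P{i + 1:03d}" for i in range(config.n_proteins - config.n_structures)
    ]
    n = len(proteins)

    gamma = config.interactome_degree_exponent
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** (-1.0 / (gamma - 1.0))
    target_mean_degree = 6.0
    weights *= target_mean_degree * n / weights.sum()
    order = rng.permutation(n)  # decouple degree rank from protein naming
    w = np.empty(n)
    w[order] = weights
    total = w.sum()

    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    for i in range(n):
        for j in range(i + 1, n):
            p = min(1.0, w[i] * w[j] / total)
            if rng.random() < p:
                graph.add_edge(proteins[i], proteins[j],
                               confidence=float(np.round(rng.uniform(0.3, 1.0), 3)))

    # connect stray components to the giant component
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    anchor = sorted(comps[0])[0]
    for comp in comps[1:]:
        graph.add_edge(sorted(comp)[0], anchor,
                       confidence=float(np.round(rng.uniform(0.5, 1.0), 3)))

    # high-confidence modules around each group's signature proteins
    fillers = [p for p in proteins if not p.startswith("G")]
    modules: dict[str, list[str]] = {}
    cursor = 0
    for g in config.group_spec:
        sig_proteins = sorted({lab.split(":", 1)[1] for lab in g.signature_patches})
        partners = fillers[cursor:cursor + 3]
        cursor += 3
        module = sig_proteins + partners
        # signature proteins talk through shared partners, never directly,
        # so reconstructed networks must include the module partners
        for a in sig_proteins:
            if graph.has_edge(a, sig_proteins[0]) and a != sig_proteins[0]:
                graph.remove_edge(a, sig_proteins[0])
            for b in partners:
                graph.add_edge(a, b, confidence=0.9)
        for a, b in zip(partners, partners[1:]):
            graph.add_edge(a, b, confidence=0.9)
        modules[g.group_id] = module

    # pathways
    pathways: dict[str, set[str]] = {}
    lo, hi = config.pathway_size_range
    for g in config.group_spec:
        members = set(modules[g.group_id])
        size = min(int(rng.integers(lo, hi + 1)), n)
        pad = [p for p in proteins if p not in members]
        n_extra = min(max(0, size - len(members)), len(pad))
        extra = rng.choice(len(pad), size=n_extra, replace=False)
        members |= {pad[i] for i in sorted(extra.tolist())}
        pathways[f"{g.group_id} signaling pathway"] = members
    n_background = max(0, config.n_pathways - len(config.group_spec) - 2)
    for i in range(n_background):
        size = min(int(rng.integers(lo, hi + 1)), n)
        idx = rng.choice(n, size=size, replace=False)
        pathways[f"background pathway {i + 1}"] = {proteins[j] for j in sorted(idx.tolist())}
    for i, name in enumerate(("pan-cancer pathway", "viral infection pathway")):
        size = min(int(rng.integers(lo, hi + 1)), n)
        idx = rng.choice(n, size=size, replace=False)
        pathways[name] = {proteins[j] for j in sorted(idx.tolist())}
    return graph, pathways


# ---------------------------------------------------------------------------
# cell lines


def generate_cell_lines(
    config: SyntheticConfig,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell-line mutation, drug-response and drug-target tables.

    Each line carries a random subset of the planted patches (sampling one
    or more member sites per carried patch) plus background singleton
    mutations. A drug mapped to a patch in ``drug_effect_map`` gets the
    mapped response label on every line carrying that patch and a random
    label elsewhere; the mapped drug targets its patch's protein.
    """
    labels = set(truth.patch_members)
    for drug, patch_label, effect in config.drug_effect_map:
        if patch_label not in labels:
            raise ValueError(f"drug_effect_map references unknown patch {patch_label}")
        if effect not in ("sensitive", "resistant"):
            raise ValueError(f"invalid effect {effect!r}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lines = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    mut_rows, resp_rows, target_rows = [], [], []
    patch_labels = sorted(truth.patch_members)

    mapped_by_drug: dict[str, tuple[str, str]] = {
        drug: (patch_label, effect) for drug, patch_label, effect in config.drug_effect_map
    }
    drugs = sorted(mapped_by_drug) + [f"drug-bg{i + 1}" for i in range(2)]

    for line in lines:
        carried: set[str] = set()
        for label in patch_labels:
            if rng.random() < 0.4:
                carried.add(label)
                sites = sorted(truth.patch_members[label])
                k = 1 + int(rng.integers(min(2, len(sites))))
                for i in sorted(rng.choice(len(sites), size=k, replace=False).tolist()):
                    protein, pos = sites[i]
                    mut_rows.append({"cell_line": line, "protein": protein,
                                     "position": pos, "alt_aa": "X"})
        truth.cell_line_patches[line] = carried
        singles = sorted(truth.singletons)
        if singles:
            for i in sorted(rng.choice(len(singles), size=min(3, len(singles)),
                                       replace=False).tolist()):
                protein, pos = singles[i]
                mut_rows.append({"cell_line": line, "protein": protein,
                                 "position": pos, "alt_aa": "X"})
        for drug in drugs:
            if drug in mapped_by_drug and mapped_by_drug[drug][0] in carried:
                label = mapped_by_drug[drug][1]
            else:
                label = "sensitive" if rng.random() < 0.5 else "resistant"
            resp_rows.append({"cell_line": line, "drug": drug, "response": label})

    for drug in drugs:
        if drug in mapped_by_drug:
            target = mapped_by_drug[drug][0].split(":", 1)[1]
        else:
            target = f"P{int(rng.integers(1, config.n_proteins - config.n_structures)):03d}"
        target_rows.append({"drug": drug, "target": target})

    return (
        pd.DataFrame(mut_rows, columns=["cell_line", "protein", "position", "alt_aa"]),
        pd.DataFrame(resp_rows, columns=["cell_line", "drug", "response"]),
        pd.DataFrame(target_rows, columns=["drug", "target"]),
    )


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    structures: dict[str, Structure]
    mutations: list[MutationRecord]
    clinical: pd.DataFrame
    interactome: nx.Graph
    pathways: dict[str, set[str]]
    cell_line_mutations: pd.DataFrame
    drug_response: pd.DataFrame
    drug_targets: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        from .netrecon import write_interactome
        from .stratify import write_gmt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for protein, structure in sorted(self.structures.items()):
            (outdir / f"{protein}.pdb").write_text(write_pdb(structure))
        write_mutation_table(self.mutations, outdir / "mutations.tsv")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        write_interactome(self.interactome, outdir / "interactome.tsv")
        write_gmt(self.pathways, outdir / "pathways.gmt")
        self.cell_line_mutations.to_csv(
            outdir / "cell_line_mutations.tsv", sep="\t", index=False)
        self.drug_response.to_csv(outdir / "drug_response.tsv", sep="\t", index=False)
        self.drug_targets.to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)
        (outdir / "ground_truth.json").write_text(self.truth.to_json())


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic study from one config (deterministic)."""
    config = config or SyntheticConfig()
    structures = {
        protein: generate_structure(
            config.residues_per_structure,
            seed=int(np.random.SeedSequence([config.seed, 0, i]).generate_state(1)[0]),
            protein=protein,
        )
        for i, protein in enumerate(config.structured_proteins)
    }
    mutations, clinical, truth = plant_cohort(config, structures)
    interactome, pathways = generate_interactome(config, truth)
    cl_mut, cl_resp, cl_targets = generate_cell_lines(config, truth)
    return SyntheticCohort(
        config, structures, mutations, clinical, interactome, pathways,
        cl_mut, cl_resp, cl_targets, truth,
    )


# ---------------------------------------------------------------------------
# mutation table I/O (MAF-like TSV)

_MUTATION_COLUMNS = [
    "patient_id", "protein", "position", "ref_aa", "alt_aa",
    "mutation_type", "is_driver", "is_significant", "gene_role",
]


def write_mutation_table(mutations: Sequence[MutationRecord], path) -> None:
    rows = [
        {
            "patient_id": m.patient, "protein": m.protein, "position": m.position,
            "ref_aa": m.ref_aa, "alt_aa": m.alt_aa, "mutation_type": m.mutation_type,
            "is_driver": int(m.is_driver), "is_significant": int(m.is_significant),
            "gene_role": m.gene_role,
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=_MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_table(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        MutationRecord(
            patient=str(r.patient_id), protein=str(r.protein), position=int(r.position),
            ref_aa=str(r.ref_aa), alt_aa=str(r.alt_aa),
            mutation_type=str(r.mutation_type),
            is_driver=bool(int(r.is_driver)), is_significant=bool(int(r.is_significant)),
            gene_role=str(r.gene_role),
        )
        for r in df.itertuples(index=False)
    ]
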