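"""Structure parsing, sequence-to-structure mapping, solvent accessibility and
core/surface/interface region classification.

Residues are addressed throughout by a *residue key* ``(chain_id, resseq)``
(author numbering; insertion codes are appended to ``resseq`` as a string when
present, e.g. ``"52A"``). Mutation positions are 1-based on the canonical
protein sequence and are translated to residue keys via
:func:`align_sequence_to_structure`.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueMapping",
    "RegionLabel",
    "MutationRecord",
    "StructuralMutation",
    "StructureParseError",
    "ConfigurationError",
    "parse_structure",
    "write_pdb",
    "align_sequence_to_structure",
    "compute_sasa",
    "classify_regions",
    "find_interface_residues",
    "map_mutations_to_structure",
    "MAX_ASA_TIEN_2013",
    "VDW_RADII",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]


class StructureParseError(ValueError):
    """Raised for a malformed coordinate record; carries the line number."""


class ConfigurationError(KeyError):
    """Raised when a lookup table lacks a required residue type."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Theoretical maximum accessible surface areas (Å²), Tien et al. 2013.
MAX_ASA_TIEN_2013: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Van der Waals radii by element (Å); unknown elements fall back to 1.7 Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_VDW_FALLBACK = 1.70


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    chain_id: str
    resseq: str          # author residue number, insertion code appended
    resname: str         # 3-letter type
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.resseq)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """A parsed structure: an ordered list of residues grouped by chain."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def residue(self, key: tuple[str, str]) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def atom_table(self) -> tuple[np.ndarray, list[tuple[str, str]]]:
        """All atom coordinates and, per atom, the owning residue key."""
        coords, owners = [], []
        for r in self.residues:
            for a in r.atoms:
                coords.append(a.coord)
                owners.append(r.key)
        return np.asarray(coords, dtype=float), owners


@dataclass
class ResidueMapping:
    """Canonical-sequence position (1-based) -> structure residue key.

    ``identity`` is the identical fraction over aligned (non-gap) columns; a
    mapping with identity below the acceptance threshold is emptied.
    """

    protein: str
    structure_id: str
    chain_id: str
    position_to_key: dict[int, tuple[str, str]] = field(default_factory=dict)
    identity: float = 0.0

    def __len__(self) -> int:
        return len(self.position_to_key)


@dataclass(frozen=True)
class RegionLabel:
    key: tuple[str, str]
    label: str            # 'core' | 'surface' | 'interface'
    rsa: float


@dataclass(frozen=True)
class MutationRecord:
    """One patient-level amino-acid change with its annotations.

    ``alt_aa`` is a 1-letter code for missense mutations and a symbol
    (``*`` nonsense, ``fs`` frameshift) otherwise. Damage annotations
    (EVmutation score, more negative = more damaging; PolyPhen class) are
    consumed as supplied, never computed here.
    """

    patient: str
    protein: str
    position: int
    ref_aa: str
    alt_aa: str
    mutation_type: str    # 'missense' | 'nonsense' | 'frameshift'
    is_driver: bool = False
    is_significant: bool = False
    gene_role: str = ""   # 'oncogene' | 'tsg' | ''
    ev_score: float | None = None
    polyphen: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class StructuralMutation:
    """A mutation with its structure placement(s) and region label.

    ``status`` is ``mapped``, ``unmapped`` or ``ref-mismatch``; placements are
    ``(structure_id, residue_key, region_label_or_None)`` with the primary
    placement first (longest mapped structure).
    """

    record: MutationRecord
    status: str
    placements: list[tuple[str, tuple[str, str], str | None]] = field(default_factory=list)
    rsa: float | None = None

    @property
    def primary(self) -> tuple[str, tuple[str, str], str | None] | None:
        return self.placements[0] if self.placements else None

    @property
    def region(self) -> str | None:
        return self.placements[0][2] if self.placements else None


# ---------------------------------------------------------------------------
# parsing / writing


def parse_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only ATOM records of standard amino-acid residues are kept: HETATM
    records and waters are dropped. Alternate locations are resolved to the
    highest-occupancy conformer (alphabetical altloc id on ties). A malformed
    ATOM record raises :class:`StructureParseError` with its line number.
    """
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith("ATOM"):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError) as exc:
                raise StructureParseError(
                    f"malformed ATOM record at line {lineno}: {line!r}"
                ) from exc

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_struct = parser.get_structure(structure_id, io.StringIO(pdb_text))

    residues: list[Residue] = []
    model = next(iter(bio_struct), None)
    if model is None:
        return Structure(structure_id, [])
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():      # HETATM / water
                continue
            if not is_aa(res, standard=True):
                continue
            atoms = []
            for atom in res:
                # disordered atoms: Bio.PDB selects highest occupancy; on an
                # occupancy tie keep the alphabetically first altloc
                if atom.is_disordered():
                    children = sorted(
                        atom.child_dict.items(),
                        key=lambda kv: (-(kv[1].get_occupancy() or 0.0), kv[0]),
                    )
                    atom = children[0][1]
                element = (atom.element or "").strip().upper() or atom.get_name()[0]
                atoms.append(Atom(atom.get_name(), element, tuple(float(x) for x in atom.get_coord())))
            key_resseq = f"{resseq}{icode.strip()}"
            residues.append(Residue(chain.id, key_resseq, res.get_resname(), tuple(atoms)))
    return Structure(structure_id, residues)


def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` to PDB-format text (ATOM records only)."""
    lines = []
    serial = 1
    for res in structure.residues:
        resseq = res.resseq
        icode = " "
        if resseq and not resseq.lstrip("-").isdigit():
            icode = resseq[-1]
            resseq = resseq[:-1]
        for atom in res.atoms:
            x, y, z = atom.coord
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {res.resname:<3s} {res.chain_id:1.1s}"
                f"{int(resseq):4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequence-structure mapping


def chain_sequence(structure: Structure, chain_id: str) -> tuple[str, list[tuple[str, str]]]:
    """1-letter sequence of a chain and the residue key per position."""
    seq, keys = [], []
    for res in structure.chain(chain_id):
        one = THREE_TO_ONE.get(res.resname)
        if one is None:
            continue
        seq.append(one)
        keys.append(res.key)
    return "".join(seq), keys


def align_sequence_to_structure(
    canonical_seq: str,
    structure: Structure,
    chain_id: str,
    protein: str = "",
    min_identity: float = 0.9,
) -> ResidueMapping:
    """Globally align the canonical sequence to a chain's observed sequence.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -0.5. The mapping
    covers aligned non-gap columns only (identical or substituted); it is
    rejected (emptied) when identity over aligned columns falls below
    ``min_identity``, since residue numbering in deposited structures often
    disagrees with canonical sequence positions.
    """
    struct_seq, keys = chain_sequence(structure, chain_id)
    if not canonical_seq or not struct_seq:
        raise ValueError("both sequences must be non-empty")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # do not penalize terminal gaps: the structure may cover a fragment
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0

    alignment = aligner.align(canonical_seq, struct_seq)[0]
    mapping: dict[int, tuple[str, str]] = {}
    n_aligned = n_identical = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            i, j = t0 + offset, q0 + offset
            n_aligned += 1
            if canonical_seq[i] == struct_seq[j]:
                n_identical += 1
            mapping[int(i) + 1] = keys[j]

    identity = n_identical / n_aligned if n_aligned else 0.0
    result = ResidueMapping(protein, structure.id, chain_id, mapping, identity)
    if identity < min_identity:
        logger.info(
            "mapping %s -> %s/%s rejected: identity %.3f < %.3f",
            protein, structure.id, chain_id, identity, min_identity,
        )
        result.position_to_key = {}
    return result


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (Fibonacci lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[tuple[str, str], float]:
    """Per-residue absolute solvent-accessible surface area (Å²).

    Shrake–Rupley: each atom is expanded by the probe radius and sampled with
    ``n_sphere_points`` quasi-uniform sphere points; the accessible fraction is
    the fraction of points outside every neighbouring expanded sphere.
    Per-residue SASA sums the atom values.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords, owners = structure.atom_table()
    elements = [a.element for r in structure.residues for a in r.atoms]
    radii = np.array([VDW_RADII.get(e, _VDW_FALLBACK) + probe_radius for e in elements])

    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    sasa: dict[tuple[str, str], float] = {r.key: 0.0 for r in structure.residues}

    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        sasa[owners[i]] += frac * 4.0 * math.pi * radii[i] ** 2
    return sasa


# ---------------------------------------------------------------------------
# regions


def find_interface_residues(
    complex_structure: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
) -> dict[str, set[tuple[str, str]]]:
    """Interface residues of a binary complex.

    A residue of one chain is an interface residue iff any of its atoms lies
    within ``cutoff`` Å of any atom of the partner chain (strict inequality,
    matching the residue-contact rule).
    """
    for cid in (chain_a, chain_b):
        if not complex_structure.chain(cid):
            raise ValueError(f"chain {cid!r} not present in {complex_structure.id}")

    def _chain_atoms(cid: str) -> tuple[np.ndarray, list[tuple[str, str]]]:
        coords, owners = [], []
        for res in complex_structure.chain(cid):
            for atom in res.atoms:
                coords.append(atom.coord)
                owners.append(res.key)
        return np.asarray(coords, dtype=float), owners

    ca, oa = _chain_atoms(chain_a)
    cb, ob = _chain_atoms(chain_b)
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff - 1e-12)
    out: dict[str, set[tuple[str, str]]] = {chain_a: set(), chain_b: set()}
    for i, js in enumerate(pairs):
        if not js:
            continue
        d = np.linalg.norm(cb[js] - ca[i], axis=1)
        close = [j for j, dist in zip(js, d) if dist < cutoff]
        if close:
            out[chain_a].add(oa[i])
            for j in close:
                out[chain_b].add(ob[j])
    return out


MIN_STRUCTURE_LENGTH = 50  # structures of <= this many residues carry no labels


def classify_regions(
    structure: Structure,
    sasa: Mapping[tuple[str, str], float],
    interface_residues: Iterable[tuple[str, str]] = (),
    max_asa_table: Mapping[str, float] | None = None,
) -> dict[tuple[str, str], RegionLabel]:
    """Label every residue core / surface / interface.

    Relative SASA (RSA) = absolute SASA (monomer state) / maximum ASA of the
    residue type. Interface membership overrides the RSA rule; otherwise
    RSA >= 0.05 is surface and the rest core. Structures with 50 or fewer
    residues are skipped (too small for reliable burial statistics) and
    return no labels.
    """
    if max_asa_table is None:
        max_asa_table = MAX_ASA_TIEN_2013
    if len(structure) <= MIN_STRUCTURE_LENGTH:
        logger.info("structure %s has %d residues (<= %d): skipped",
                    structure.id, len(structure), MIN_STRUCTURE_LENGTH)
        return {}
    interface = set(interface_residues)
    labels: dict[tuple[str, str], RegionLabel] = {}
    for res in structure.residues:
        if res.resname not in max_asa_table:
            raise ConfigurationError(
                f"residue type {res.resname} missing from max-ASA table")
        rsa = sasa[res.key] / max_asa_table[res.resname]
        if res.key in interface:
            label = "interface"
        elif rsa >= 0.05:
            label = "surface"
        else:
            label = "core"
        labels[res.key] = RegionLabel(res.key, label, rsa)
    return labels


# ---------------------------------------------------------------------------
# mutation mapping


def map_mutations_to_structure(
    mutations: Sequence[MutationRecord],
    mappings: Sequence[ResidueMapping],
    regions: Mapping[str, Mapping[tuple[str, str], RegionLabel]],
    structures: Mapping[str, Structure] | None = None,
) -> list[StructuralMutation]:
    """Place each mutation on every structure its protein maps to.

    ``regions`` is keyed by structure id. A mutation mapping to several
    structures keeps all placements; the primary placement is the one on the
    longest mapped structure. If ``structures`` is given, the reference amino
    acid of the record is checked against the mapped structure residue and
    disagreements are flagged ``ref-mismatch`` and excluded from structural
    analyses.
    """
    by_protein: dict[str, list[ResidueMapping]] = {}
    for m in mappings:
        by_protein.setdefault(m.protein, []).append(m)

    out: list[StructuralMutation] = []
    for rec in mutations:
        placements: list[tuple[str, tuple[str, str], str | None, int]] = []
        mismatch = False
        for m in by_protein.get(rec.protein, []):
            key = m.position_to_key.get(rec.position)
            if key is None:
                continue
            if structures is not None and m.structure_id in structures:
                res = structures[m.structure_id].residue(key)
                if THREE_TO_ONE.get(res.resname) != rec.ref_aa:
                    mismatch = True
                    continue
            label = None
            reg = regions.get(m.structure_id)
            if reg and key in reg:
                label = reg[key].label
            placements.append((m.structure_id, key, label, len(m)))
        if placements:
            placements.sort(key=lambda p: (-p[3], p[0]))
            sm = StructuralMutation(rec, "mapped", [p[:3] for p in placements])
            reg = regions.get(placements[0][0], {})
            lbl = reg.get(placements[0][1])
            sm.rsa = lbl.rsa if lbl else None
            out.append(sm)
        elif mismatch:
            logger.info("ref-mismatch: %s %s%d", rec.protein, rec.ref_aa, rec.position)
            out.append(StructuralMutation(rec, "ref-mismatch"))
        else:
            out.append(StructuralMutation(rec, "unmapped"))
    return out
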