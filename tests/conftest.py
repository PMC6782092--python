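"""Shared fixtures: tiny hand-built structures and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from patchnet.structmap import Atom, Residue, Structure
from patchnet.synthcohort import SyntheticConfig, generate_cohort


def make_structure(
    coords,
    chain_id: str = "A",
    resnames=None,
    structure_id: str = "toy",
    start: int = 1,
) -> Structure:
    """Build a structure with one atom per residue at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    resnames = resnames or ["ALA"] * len(coords)
    residues = [
        Residue(
            chain_id,
            str(start + i),
            resnames[i],
            (Atom("CA", "C", tuple(coords[i])),),
        )
        for i in range(len(coords))
    ]
    return Structure(structure_id, residues)


def chain_structure(n: int, spacing: float = 3.8, **kwargs) -> Structure:
    """A straight chain of single-atom residues ``spacing`` Å apart."""
    return make_structure([(i * spacing, 0.0, 0.0) for i in range(n)], **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticConfig(seed=11))
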