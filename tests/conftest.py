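"""Shared fixtures: tiny deterministic crystals and brute-force helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nmrxtal import (
    CrystalStructure,
    SiteGroup,
    SyntheticSpec,
    UnitCell,
    fractional_contacts_model,
    make_structure,
)
from nmrxtal.crystal import ANGSTROM_TO_PM, frac_to_cartesian


@pytest.fixture
def two_spin_structure() -> CrystalStructure:
    """One 31P and one 1H, 250 pm apart along a, in a 2000 pm cubic cell."""
    spec = SyntheticSpec(
        cell=UnitCell(20.0, 20.0, 20.0),
        coords={
            "P1": ("31P", (0.0, 0.0, 0.0)),
            "H1": ("1H", (0.125, 0.0, 0.0)),
        },
    )
    return make_structure(spec)


def make_bonded_structure() -> CrystalStructure:
    """One 31P with three protons at bonded-to-close-contact distances
    (250/300/350 pm) in a 10 angstrom cubic cell.  Every pair class is
    dominated by its short direct contact, so the r^-6 lattice sums
    converge quickly with cutoff."""
    spec = SyntheticSpec(
        cell=UnitCell(10.0, 10.0, 10.0),
        coords={
            "P1": ("31P", (0.0, 0.0, 0.0)),
            "H1": ("1H", (0.25, 0.0, 0.0)),
            "H2": ("1H", (0.0, 0.30, 0.0)),
            "H3": ("1H", (0.0, 0.0, 0.35)),
        },
    )
    return make_structure(spec)


def random_p1_structure(seed: int, n_h: int = 4, cell_angstrom: float = 8.0) -> CrystalStructure:
    """A reproducible random P1 crystal: one 31P plus ``n_h`` protons."""
    spec = SyntheticSpec(
        cell=UnitCell(cell_angstrom, cell_angstrom, cell_angstrom),
        species_counts={"31P": 1, "1H": n_h},
        min_separation_pm=180.0,
        seed=seed,
    )
    return make_structure(spec)


def heteronuclear_pairs(structure: CrystalStructure) -> list[tuple[str, str]]:
    p = next(g.id for g in structure.groups.values() if g.species == "31P")
    return [(p, g.id) for g in structure.groups.values() if g.species == "1H"]


def model_contacts(structure: CrystalStructure, cutoff_pm: float = 1000.0):
    return fractional_contacts_model(structure, heteronuclear_pairs(structure), cutoff_pm=cutoff_pm)


def supercell_distances(
    structure: CrystalStructure, group_j: str, group_k: str, cutoff_pm: float
) -> np.ndarray:
    """Oracle: distances via an explicit supercell double loop (sorted, pm)."""
    cell = structure.cell
    gj = structure.group(group_j)
    gk = structure.group(group_k)
    frac = {s.label: np.array(s.frac) for s in structure.sites}
    cutoff_angstrom = cutoff_pm / ANGSTROM_TO_PM
    n = [int(math.ceil(cutoff_angstrom / length)) + 2 for length in (cell.a, cell.b, cell.c)]
    same = group_j == group_k
    out = []
    for a in gj.member_labels:
        pa = frac_to_cartesian(cell, frac[a])
        for b in gk.member_labels:
            for ix in range(-n[0], n[0] + 1):
                for iy in range(-n[1], n[1] + 1):
                    for iz in range(-n[2], n[2] + 1):
                        pb = frac_to_cartesian(cell, frac[b] + np.array([ix, iy, iz]))
                        r = float(np.linalg.norm(pa - pb)) * ANGSTROM_TO_PM
                        if 0 < r <= cutoff_pm:
                            out.append(r)
    out = np.sort(np.array(out))
    if same:
        return out[::2]  # every unordered contact appears exactly twice
    return out


def make_group(structure: CrystalStructure, gid: str, labels: list[str], species: str, **kw):
    groups = dict(structure.groups)
    groups[gid] = SiteGroup(id=gid, member_labels=tuple(labels), species=species, **kw)
    return structure.with_groups(groups.values())
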