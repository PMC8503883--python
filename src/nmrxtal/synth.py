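"""Synthetic crystal structures and peak tables with known ground truth.

Every stochastic generator takes an explicit seed and is reproducible
across platforms (NumPy PCG64).  The module also hosts the brute-force
supercell lattice-sum oracle used to cross-check the image-shell
enumeration and the effective-coupling sums: a plain double loop over an
explicitly replicated supercell, with no symmetry or neighbour-list
shortcuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import dipolar_constant
from .crystal import (
    ANGSTROM_TO_PM,
    AtomSite,
    CrystalStructure,
    SiteGroup,
    UnitCell,
    frac_to_cartesian,
)
from .dipolar import ContactSet
from .peaks import PeakRecord, PeakTable

__all__ = ["SyntheticSpec", "make_structure", "make_peak_table", "brute_force_beff"]

Pair = tuple[str, str]

_SPECIES_ELEMENT = {"1H": "H", "13C": "C", "31P": "P", "15N": "N", "19F": "F", "29Si": "Si"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic P1 crystal of spin-1/2 sites.

    Sites are either placed explicitly (``coords``: label -> fractional
    triple) or uniformly at random subject to a minimum separation that is
    enforced across periodic images.  Each site becomes its own site
    group, the finest grouping; coarser groups can be attached afterwards.
    """

    cell: UnitCell
    species_counts: Mapping[str, int] = field(default_factory=dict)
    coords: Mapping[str, tuple[str, tuple[float, float, float]]] | None = None
    min_separation_pm: float = 150.0
    seed: int | None = None
    max_tries: int = 2000

    def __post_init__(self) -> None:
        if self.min_separation_pm <= 0:
            raise ValueError("minimum separation must be positive")
        if self.coords is None and self.seed is None:
            raise ValueError("a seed is mandatory for random placement")
        if self.coords is None and not self.species_counts:
            raise ValueError("specify species_counts or explicit coords")


def _min_image_dist_pm(cell: UnitCell, fa: np.ndarray, fb: np.ndarray) -> float:
    """Minimum distance over the 27 neighbouring images (valid because the
    placement constraint only needs a lower bound on short contacts)."""
    best = math.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                d = frac_to_cartesian(cell, fa - fb + np.array([sx, sy, sz]))
                best = min(best, float(np.linalg.norm(d)))
    return best * ANGSTROM_TO_PM


def _shortest_lattice_pm(cell: UnitCell) -> float:
    """Length of the shortest nonzero lattice vector in the 27-cell shell:
    the distance between an atom and its own nearest periodic image."""
    best = math.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                if (sx, sy, sz) == (0, 0, 0):
                    continue
                v = frac_to_cartesian(cell, np.array([sx, sy, sz], dtype=float))
                best = min(best, float(np.linalg.norm(v)))
    return best * ANGSTROM_TO_PM


def make_structure(spec: SyntheticSpec) -> CrystalStructure:
    """Generate the structure described by ``spec`` (P1, one group per site)."""
    sites: list[AtomSite] = []
    if spec.coords is not None:
        for label, (species, frac) in spec.coords.items():
            sites.append(
                AtomSite(
                    label=label,
                    element=_SPECIES_ELEMENT.get(species, species),
                    frac=tuple(frac),
                    spin_species=species,
                )
            )
    else:
        rng = np.random.default_rng(spec.seed)
        if _shortest_lattice_pm(spec.cell) < spec.min_separation_pm:
            raise RuntimeError(
                "cell is smaller than the minimum separation: every site "
                "would clash with its own periodic image; use a larger cell"
            )
        placed: list[np.ndarray] = []
        for species, count in spec.species_counts.items():
            for i in range(count):
                for _ in range(spec.max_tries):
                    f = rng.uniform(0.0, 1.0, size=3)
                    if all(
                        _min_image_dist_pm(spec.cell, f, p) >= spec.min_separation_pm
                        for p in placed
                    ):
                        placed.append(f)
                        break
                else:
                    raise RuntimeError(
                        f"could not place {species} site {i + 1} after "
                        f"{spec.max_tries} tries; use a larger cell or fewer sites"
                    )
                label = f"{_SPECIES_ELEMENT.get(species, species)}{len(sites) + 1}"
                sites.append(
                    AtomSite(
                        label=label,
                        element=_SPECIES_ELEMENT.get(species, species),
                        frac=tuple(placed[-1]),
                        spin_species=species,
                    )
                )
    groups = {
        s.label: SiteGroup(id=s.label, member_labels=(s.label,), species=s.spin_species)
        for s in sites
        if s.spin_species is not None
    }
    return CrystalStructure(cell=spec.cell, sites=sites, groups=groups)


def make_peak_table(
    contacts: ContactSet,
    sigma_rel: float = 0.0,
    seed: int | None = None,
) -> PeakTable:
    """Emulate a quantitative 2D spectrum from model contacts.

    Intensities are proportional to b_eff^2 with multiplicative lognormal
    noise (integration error is scale-proportional): I = b_eff^2 *
    exp(sigma_rel * z), z ~ N(0, 1).  ``sigma_rel = 0`` reproduces the
    model fractions exactly.
    """
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be >= 0")
    if sigma_rel > 0 and seed is None:
        raise ValueError("a seed is mandatory for noisy generation")
    rng = np.random.default_rng(seed)
    records = []
    for pair, eff in contacts.couplings.items():
        noise = float(np.exp(sigma_rel * rng.standard_normal())) if sigma_rel > 0 else 1.0
        kind = "heteronuclear"
        if eff.species == ("1H", "1H"):
            kind = "2Q-autocorrelation" if pair[0] == pair[1] else "2Q-cross"
        records.append(
            PeakRecord(
                pair=pair,
                intensity=eff.b_eff_sq * noise,
                kind=kind,
                sigma_rel=sigma_rel,
                excluded=eff.excluded,
                reason=eff.exclude_reason,
            )
        )
    return PeakTable(records=records)


def brute_force_beff(
    structure: CrystalStructure,
    group_j: str,
    group_k: str,
    cutoff_pm: float = 1000.0,
    motional_scale: float = 1.0,
) -> float:
    """Oracle lattice sum: b_eff^2 by an explicit supercell double loop.

    Replicates the P1 cell out to a supercell that covers the cutoff and
    sums K^2/r^6 over every atom pair of the two groups, counting each
    unordered pair once for a homonuclear self-pair.  Intended for small
    structures (<= ~100 sites).
    """
    if not structure.is_p1:
        raise ValueError("oracle expects a P1 structure")
    gj = structure.group(group_j)
    gk = structure.group(group_k)
    cell = structure.cell
    cutoff_angstrom = cutoff_pm / ANGSTROM_TO_PM
    n = [
        int(math.ceil(cutoff_angstrom / length)) + 2
        for length in (cell.a, cell.b, cell.c)
    ]
    frac = {s.label: np.array(s.frac) for s in structure.sites}
    k_const = dipolar_constant(gj.species, gk.species)
    same = group_j == group_k
    total = 0.0
    for a in gj.member_labels:
        fa = frac[a]
        pa = frac_to_cartesian(cell, fa)
        for b in gk.member_labels:
            fb = frac[b]
            for ix in range(-n[0], n[0] + 1):
                for iy in range(-n[1], n[1] + 1):
                    for iz in range(-n[2], n[2] + 1):
                        shift = np.array([ix, iy, iz], dtype=float)
                        pb = frac_to_cartesian(cell, fb + shift)
                        r_pm = float(np.linalg.norm(pa - pb)) * ANGSTROM_TO_PM
                        if r_pm <= 0 or r_pm > cutoff_pm:
                            continue
                        total += (k_const / r_pm**3) ** 2
    if same:
        total /= 2.0  # every unordered contact was visited twice
    return motional_scale**2 * total
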