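"""Physical constants and the spin-species registry.

All dipolar arithmetic in the package funnels through :func:`dipolar_constant`
so that the unit conventions (distances in pm, couplings in rad/s) are fixed
in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import hbar as HBAR  # J s
from scipy.constants import mu_0 as MU0  # N A^-2

#: pm^3 per m^3, used to express the dipolar constant with r in pm.
_M3_TO_PM3 = 1e36

TWO_PI = 6.283185307179586


@dataclass(frozen=True)
class SpinSpecies:
    """An NMR-active nuclide.

    Parameters
    ----------
    name:
        Conventional isotope label, e.g. ``"1H"``.
    gamma:
        Magnetogyric ratio in rad s^-1 T^-1 (CODATA/IUPAC).
    spin:
        Spin quantum number; the distance analysis assumes 1/2.
    """

    name: str
    gamma: float
    spin: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma == 0:
            raise ValueError(f"gamma must be nonzero for species {self.name!r}")


#: Immutable registry of the nuclides handled by default.
SPECIES: dict[str, SpinSpecies] = {
    "1H": SpinSpecies("1H", 2.6752218744e8),
    "13C": SpinSpecies("13C", 6.728284e7),
    "31P": SpinSpecies("31P", 1.08394e8),
    "15N": SpinSpecies("15N", -2.71261804e7),
    "19F": SpinSpecies("19F", 2.518148e8),
    "29Si": SpinSpecies("29Si", -5.3190e7),
}

#: Default NMR-active nuclide assumed for an element symbol found in a CIF.
ELEMENT_DEFAULT_SPECIES: dict[str, str] = {
    "H": "1H",
    "C": "13C",
    "P": "31P",
    "N": "15N",
    "F": "19F",
    "Si": "29Si",
}


def get_species(name: str) -> SpinSpecies:
    try:
        return SPECIES[name]
    except KeyError:
        raise KeyError(
            f"unknown spin species {name!r}; known: {sorted(SPECIES)}"
        ) from None


def dipolar_constant(species_a: str | SpinSpecies, species_b: str | SpinSpecies) -> float:
    """Dipolar constant K = -(mu0/4pi) * gamma_a * gamma_b * hbar.

    Returned in rad s^-1 pm^3, so that the pairwise coupling is
    ``b = K / r**3`` with ``r`` in pm.  The physical sign convention
    (negative for two positive-gamma nuclei) is kept; only K**2 enters
    the distance analysis.
    """
    a = get_species(species_a) if isinstance(species_a, str) else species_a
    b = get_species(species_b) if isinstance(species_b, str) else species_b
    return -(MU0 / (4.0 * 3.141592653589793)) * a.gamma * b.gamma * HBAR * _M3_TO_PM3
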