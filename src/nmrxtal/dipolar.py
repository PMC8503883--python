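"""Effective dipolar couplings, fractional dipolar contacts, and
effective internuclear distances.

The quantities computed here link a crystal-structure model to the 2D NMR
observables.  For a pair class (S^j, H^k) of magnetically unique sites the
squared *effective* coupling is the multiplicity-limited lattice sum

    b_eff^2(j,k) = s^2 * sum_{n=1..M} b^2(r_n),      b(r) = K_SH / r^3,

over the M shortest j-k contacts (the dipolar multiplicity), with s the
motional scaling of the pair (e.g. 1/2 for intra-amino 1H-1H under fast
NH3 rotation).  b_eff^2 is directly proportional to the van Vleck dipolar
second moment of the pair class.  The total over all pair classes,
b_tot^2 = sum b_eff^2, normalizes the *fractional dipolar contacts*
f(j,k) = b_eff^2 / b_tot^2, which are the model-side counterparts of the
fractional 2D NMR peak intensities.

Each b_eff^2 maps back to one *effective distance*: the inverse-sixth-power
mean of the summed contact set,

    r_eff = [ M * K_SH^2 * s^2 / b_eff^2 ]^(1/6) = [ M / sum r_n^-6 ]^(1/6),

which lies between the shortest and longest contributing distances, closer
to the shortest.  The multiplicity normalization (the power mean, rather
than a raw inverse sum) is what guarantees that bracketing; the raw sum is
also exposed for diagnostic use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import TWO_PI, dipolar_constant
from .crystal import CrystalStructure, DistanceList, enumerate_distances

__all__ = [
    "EffectiveCoupling",
    "ContactSet",
    "coupling_constant",
    "effective_coupling_sq",
    "total_coupling_sq",
    "fractional_contacts_model",
    "effective_distance",
    "single_pair_reference",
]

Pair = tuple[str, str]


def coupling_constant(species_a: str, species_b: str, r_pm: float) -> float:
    """Pairwise dipolar coupling constant b = K / r^3 in rad/s (r in pm).

    Carries the physical sign of K; only b**2 enters the distance analysis.
    Divide by 2*pi for Hz.
    """
    if r_pm <= 0:
        raise ValueError(f"internuclear distance must be positive, got {r_pm}")
    return dipolar_constant(species_a, species_b) / r_pm**3


@dataclass(frozen=True)
class EffectiveCoupling:
    """Multiplicity-summed squared coupling for one site-pair class."""

    pair: Pair
    species: tuple[str, str]
    m_pair: int
    b_eff_sq: float  # rad^2 s^-2, motional scale included
    scale: float = 1.0
    distances: DistanceList | None = None
    excluded: bool = False
    exclude_reason: str = ""

    @property
    def k_const(self) -> float:
        return dipolar_constant(*self.species)

    @property
    def b_eff_sq_raw(self) -> float:
        """The lattice sum without the motional scaling."""
        return self.b_eff_sq / self.scale**2

    @property
    def b_eff_hz(self) -> float:
        """sqrt(b_eff^2) / 2pi, in Hz."""
        return float(np.sqrt(self.b_eff_sq) / TWO_PI)

    @property
    def r_eff_pm(self) -> float:
        return effective_distance(self)


def effective_coupling_sq(
    distances: DistanceList,
    m: int | None = None,
    motional_scale: float = 1.0,
) -> EffectiveCoupling:
    """Sum the M strongest squared couplings of a contact set.

    Parameters
    ----------
    distances:
        Sorted contact list for the pair class (self-pairs already counted
        once for homonuclear groups).
    m:
        Dipolar multiplicity: how many of the shortest contacts to sum.
        ``None`` (default) sums every contact within the list's cutoff.
    motional_scale:
        Factor applied to the coupling constants (squared in the sum).
    """
    if len(distances) == 0:
        raise ValueError(f"empty distance list for pair {distances.pair}")
    if not 0.0 < motional_scale <= 1.0:
        raise ValueError("motional_scale must be in (0, 1]")
    m_used = len(distances) if m is None else int(m)
    sel = distances.truncated(m_used)
    k = dipolar_constant(*distances.species)
    b_sq = (k / sel.r**3) ** 2
    return EffectiveCoupling(
        pair=distances.pair,
        species=distances.species,
        m_pair=m_used,
        b_eff_sq=float(motional_scale**2 * b_sq.sum()),
        scale=motional_scale,
        distances=sel,
    )


def effective_distance(eff: EffectiveCoupling) -> float:
    """Effective distance (pm) of a summed contact set.

    The -6 power mean of the contributing distances: the motional scale is
    divided out and the sum renormalized by the multiplicity, so the result
    is bracketed by the shortest and longest distances in the set.
    """
    if eff.b_eff_sq <= 0:
        raise ValueError(f"pair {eff.pair}: b_eff^2 must be positive")
    if eff.m_pair < 1:
        raise ValueError(f"pair {eff.pair}: multiplicity must be >= 1")
    k_sq = eff.k_const**2
    return float((eff.m_pair * k_sq * eff.scale**2 / eff.b_eff_sq) ** (1.0 / 6.0))


def total_coupling_sq(couplings: Iterable[EffectiveCoupling]) -> float:
    """Total squared dipolar interaction b_tot^2 over all included pair classes."""
    total = sum(c.b_eff_sq for c in couplings if not c.excluded)
    if total <= 0:
        raise ValueError("no included pair classes with positive coupling")
    return float(total)


@dataclass
class ContactSet:
    """Per-pair effective couplings with the derived totals and fractions."""

    couplings: dict[Pair, EffectiveCoupling] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.couplings:
            raise ValueError("a ContactSet needs at least one pair class")
        if all(c.excluded for c in self.couplings.values()):
            raise ValueError("all pair classes are excluded")

    @property
    def included(self) -> dict[Pair, EffectiveCoupling]:
        return {p: c for p, c in self.couplings.items() if not c.excluded}

    @property
    def b_tot_sq(self) -> float:
        """Total over included pairs; excluded pairs are removed before
        normalization so the remaining fractions sum to one."""
        return total_coupling_sq(self.couplings.values())

    @property
    def f_model(self) -> dict[Pair, float]:
        tot = self.b_tot_sq
        return {p: c.b_eff_sq / tot for p, c in self.included.items()}

    @property
    def r_eff_model(self) -> dict[Pair, float]:
        return {p: effective_distance(c) for p, c in self.couplings.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: pair, M, b_eff/2pi (kHz), f, r_eff (pm)."""
        f = self.f_model
        rows = [
            {
                "group_j": p[0],
                "group_k": p[1],
                "M": c.m_pair,
                "b_eff_kHz": c.b_eff_hz / 1e3,
                "f_model": f.get(p, np.nan),
                "r_eff_pm": effective_distance(c),
                "excluded": c.excluded,
                "reason": c.exclude_reason,
            }
            for p, c in self.couplings.items()
        ]
        return pd.DataFrame(rows)


def fractional_contacts_model(
    structure: CrystalStructure,
    pairs: Iterable[Pair],
    cutoff_pm: float = 1000.0,
    multiplicity: Mapping[Pair, int] | None = None,
    motional_scales: Mapping[Pair, float] | None = None,
    exclude: Mapping[Pair, str] | None = None,
) -> ContactSet:
    """Model-side fractional dipolar contacts for the given pair classes.

    Parameters
    ----------
    structure:
        Crystal structure with the site groups defined (expanded to P1
        automatically).
    pairs:
        Pair classes ``(group_j, group_k)`` to include.
    cutoff_pm:
        Lattice-sum cutoff; contacts beyond it are ignored (the r^-6 decay
        makes the sums converge rapidly).
    multiplicity:
        Optional explicit per-pair dipolar multiplicities; pairs absent
        from the mapping sum all contacts within the cutoff.
    motional_scales:
        Optional per-pair coupling scale factors.  Defaults to the group's
        own ``motional_scale`` for homonuclear self-pairs of a
        motion-equivalent group, and 1 otherwise.
    exclude:
        Pairs to flag as excluded (with a reason); they are kept in the
        report but removed before the fractions are normalized.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pair classes requested")
    multiplicity = dict(multiplicity or {})
    motional_scales = dict(motional_scales or {})
    exclude = dict(exclude or {})
    couplings: dict[Pair, EffectiveCoupling] = {}
    for pair in pairs:
        gj, gk = pair
        scale = motional_scales.get(pair)
        if scale is None:
            group = structure.group(gj)
            if gj == gk and group.equivalent_by_motion:
                scale = group.motional_scale
            else:
                scale = 1.0
        dl = enumerate_distances(structure, gj, gk, cutoff_pm=cutoff_pm)
        eff = effective_coupling_sq(dl, m=multiplicity.get(pair), motional_scale=scale)
        if pair in exclude:
            eff = EffectiveCoupling(
                pair=eff.pair,
                species=eff.species,
                m_pair=eff.m_pair,
                b_eff_sq=eff.b_eff_sq,
                scale=eff.scale,
                distances=eff.distances,
                excluded=True,
                exclude_reason=exclude[pair],
            )
        couplings[pair] = eff
    return ContactSet(couplings=couplings)


def single_pair_reference(
    pair: Pair,
    f_model: float,
    r_eff_pm: float,
    species: tuple[str, str] = ("31P", "1H"),
    m: int = 1,
) -> ContactSet:
    """Reconstruct a minimal reference ContactSet from one published
    (fractional contact, effective distance) row.

    Tabulated analyses quote, per pair class, the model fraction f and the
    model effective distance r_eff but not the underlying coupling sums.
    Those two numbers fix the pair's b_eff^2 = M K^2 / r_eff^6 and the
    total b_tot^2 = b_eff^2 / f; the remainder of the total is carried by
    a synthetic ``(rest, rest)`` pseudo-pair so that measured fractions
    can be mapped onto the reference with ``distances_from_intensities``.
    """
    if not 0.0 < f_model < 1.0:
        raise ValueError("f_model must lie strictly between 0 and 1")
    if r_eff_pm <= 0:
        raise ValueError("r_eff_pm must be positive")
    k_sq = dipolar_constant(*species) ** 2
    b_eff_sq = m * k_sq / r_eff_pm**6
    b_tot_sq = b_eff_sq / f_model
    couplings = {
        pair: EffectiveCoupling(pair=pair, species=species, m_pair=m, b_eff_sq=b_eff_sq),
        ("rest", "rest"): EffectiveCoupling(
            pair=("rest", "rest"),
            species=species,
            m_pair=1,
            b_eff_sq=b_tot_sq - b_eff_sq,
        ),
    }
    return ContactSet(couplings=couplings)
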