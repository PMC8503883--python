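"""Periodic crystal structures and interatomic-distance enumeration.

This module represents a crystal as a unit cell, a set of symmetry
operators, and atom sites with fractional coordinates, and enumerates all
interatomic contacts between two site groups out to a cutoff, including
intermolecular contacts across periodic images.  Distances are carried in
pm throughout the package; CIF lengths (angstrom) are converted on read.

The image search is an explicit integer-shell enumeration sized to cover
the cutoff, not a minimum-image search: the relevant cutoffs (>= 1 nm)
routinely exceed half the cell edges of small-molecule crystals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np

from .constants import ELEMENT_DEFAULT_SPECIES

__all__ = [
    "UnitCell",
    "AtomSite",
    "SiteGroup",
    "SymOp",
    "CrystalStructure",
    "DistanceEntry",
    "DistanceList",
    "read_cif",
    "expand_to_p1",
    "frac_to_cartesian",
    "enumerate_distances",
]

#: Cartesian tolerance (angstrom) below which two symmetry images are the
#: same atom: far below any physical interatomic distance, above FP noise.
DEDUP_TOL_ANGSTROM = 0.01

ANGSTROM_TO_PM = 100.0


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (angstrom) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie strictly in (0, 180) degrees")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise ValueError("cell parameters give a non-positive volume")

    @property
    def matrix(self) -> np.ndarray:
        """Orthogonalization matrix; columns are the lattice vectors in angstrom.

        Standard crystallographic convention: **a** along x, **b** in the
        xy-plane.  ``matrix @ frac`` maps fractional to Cartesian coordinates.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        ax = self.a
        bx, by = self.b * cg, self.b * sg
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz = math.sqrt(max(self.c**2 - cx**2 - cy**2, 0.0))
        return np.array([[ax, bx, cx], [0.0, by, cy], [0.0, 0.0, cz]])

    @property
    def volume(self) -> float:
        """Cell volume in cubic angstrom."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(arg, 0.0))


def frac_to_cartesian(cell: UnitCell, frac: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map fractional coordinates to Cartesian (angstrom).

    Accepts a single triple or an (N, 3) array.
    """
    frac = np.asarray(frac, dtype=float)
    return frac @ cell.matrix.T


def cartesian_to_frac(cell: UnitCell, cart: Sequence[float] | np.ndarray) -> np.ndarray:
    cart = np.asarray(cart, dtype=float)
    return cart @ np.linalg.inv(cell.matrix).T


@dataclass(frozen=True)
class AtomSite:
    """One atom site; fractional coordinates are wrapped into [0, 1)."""

    label: str
    element: str
    frac: tuple[float, float, float]
    spin_species: str | None = None
    group_id: str | None = None

    def __post_init__(self) -> None:
        wrapped = tuple(float(x) % 1.0 for x in self.frac)
        if any(not math.isfinite(x) for x in wrapped):
            raise ValueError(f"site {self.label!r} has non-finite coordinates")
        object.__setattr__(self, "frac", wrapped)


@dataclass(frozen=True)
class SiteGroup:
    """A magnetically unique/equivalent NMR site.

    Crystallographically distinct atoms rendered equivalent by rapid motion
    (an NH3 rotor, a water molecule) form one group; ``motional_scale`` is
    the factor applied to the *coupling* (not its square) for contacts
    flagged as motionally averaged, e.g. 1/2 for intra-amino 1H-1H.
    """

    id: str
    member_labels: tuple[str, ...]
    species: str
    equivalent_by_motion: bool = False
    motional_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.member_labels:
            raise ValueError(f"group {self.id!r} has no members")
        if not 0.0 < self.motional_scale <= 1.0:
            raise ValueError(f"group {self.id!r}: motional_scale must be in (0, 1]")
        object.__setattr__(self, "member_labels", tuple(self.member_labels))


class SymOp(NamedTuple):
    """A symmetry operator acting on fractional coordinates: x' = rot @ x + tran."""

    rot: tuple[tuple[int, int, int], ...]
    tran: tuple[float, float, float]

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        """Parse e.g. ``"-x+1/2,-y,z+1/2"``."""
        try:
            op = gemmi.Op(triplet)
        except Exception as exc:  # gemmi raises RuntimeError on bad records
            raise ValueError(f"unparseable symmetry record {triplet!r}") from exc
        den = float(gemmi.Op.DEN)
        rot = tuple(tuple(int(v // gemmi.Op.DEN) for v in row) for row in op.rot)
        tran = tuple(v / den for v in op.tran)
        return cls(rot, tran)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(self.rot, dtype=float) @ frac + np.asarray(self.tran)


@dataclass
class CrystalStructure:
    """Unit cell + symmetry + atom sites + NMR site groups."""

    cell: UnitCell
    sites: list[AtomSite]
    symmetry_ops: list[SymOp] = field(default_factory=lambda: [SymOp.identity()])
    groups: dict[str, SiteGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("atom-site labels must be unique within a structure")
        for g in self.groups.values():
            missing = set(g.member_labels) - set(labels)
            if missing:
                raise ValueError(f"group {g.id!r} members not in structure: {sorted(missing)}")

    @property
    def is_p1(self) -> bool:
        return len(self.symmetry_ops) == 1 and self.symmetry_ops[0] == SymOp.identity()

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"no site labelled {label!r}")

    def group(self, group_id: str) -> SiteGroup:
        try:
            return self.groups[group_id]
        except KeyError:
            raise KeyError(
                f"unknown site group {group_id!r}; known: {sorted(self.groups)}"
            ) from None

    def with_groups(self, groups: Iterable[SiteGroup]) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell,
            sites=list(self.sites),
            symmetry_ops=list(self.symmetry_ops),
            groups={g.id: g for g in groups},
        )


class CifFormatError(ValueError):
    """Raised when a CIF lacks required records or contains unusable ones."""


def _symops_from_small_structure(st: "gemmi.SmallStructure") -> list[SymOp]:
    if st.symops:
        return [SymOp.from_triplet(op.triplet()) for op in st.symops]
    symbol = st.spacegroup_hm
    if not symbol:
        return [SymOp.identity()]
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise CifFormatError(f"unparseable space-group record {symbol!r}")
    return [SymOp.from_triplet(op.triplet()) for op in sg.operations()]


def read_cif(path: str) -> CrystalStructure:
    """Read a crystal structure from a CIF file.

    Cell parameters, symmetry (explicit operator records or a space-group
    symbol; absent symmetry means P1), fractional coordinates and type
    symbols are taken from the core dictionary.  Hydrogen sites are kept.
    Partial occupancy is rejected: this tool evaluates ordered models.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    if any(
        block.find_value(f"_cell_length_{axis}") is None for axis in ("a", "b", "c")
    ):
        raise CifFormatError(f"{path}: missing or incomplete _cell block")
    st = gemmi.read_small_structure(str(path))
    cellpars = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    cell = UnitCell(*cellpars)
    if not st.sites:
        raise CifFormatError(f"{path}: no atom sites found")
    ops = _symops_from_small_structure(st)
    sites: list[AtomSite] = []
    seen: set[str] = set()
    for raw in st.sites:
        if abs(raw.occ - 1.0) > 1e-6 and raw.occ != 0.0:
            raise CifFormatError(
                f"{path}: site {raw.label!r} has partial occupancy {raw.occ}; "
                "only ordered (occupancy-1) models are supported"
            )
        frac = (raw.fract.x, raw.fract.y, raw.fract.z)
        if any(not math.isfinite(x) for x in frac):
            raise CifFormatError(f"{path}: site {raw.label!r} lacks coordinates")
        element = raw.type_symbol or raw.element.name
        label = raw.label or f"{element}{len(sites) + 1}"
        if label in seen:
            raise CifFormatError(f"{path}: duplicate atom-site label {label!r}")
        seen.add(label)
        sites.append(
            AtomSite(
                label=label,
                element=element,
                frac=frac,
                spin_species=ELEMENT_DEFAULT_SPECIES.get(element),
            )
        )
    return CrystalStructure(cell=cell, sites=sites, symmetry_ops=ops)


def _min_image_cart_dist(cell: UnitCell, fa: np.ndarray, fb: np.ndarray) -> float:
    d = fa - fb
    d -= np.round(d)
    return float(np.linalg.norm(cell.matrix @ d))


def expand_to_p1(
    structure: CrystalStructure, tol_angstrom: float = DEDUP_TOL_ANGSTROM
) -> CrystalStructure:
    """Apply all symmetry operators and return an identity-only structure.

    Images that coincide within ``tol_angstrom`` (special positions) are
    merged.  Site groups are expanded so that every image of a member atom
    belongs to the member's group.
    """
    if structure.is_p1:
        return structure
    new_sites: list[AtomSite] = []
    image_labels: dict[str, list[str]] = {}
    for site in structure.sites:
        frac0 = np.array(site.frac)
        kept: list[np.ndarray] = []
        labels: list[str] = []
        for op in structure.symmetry_ops:
            f = op.apply(frac0) % 1.0
            if any(_min_image_cart_dist(structure.cell, f, k) < tol_angstrom for k in kept):
                continue
            label = site.label if not kept else f"{site.label}_{len(kept)}"
            kept.append(f)
            labels.append(label)
            new_sites.append(replace(site, label=label, frac=tuple(f)))
        image_labels[site.label] = labels
    new_groups = {
        g.id: replace(
            g,
            member_labels=tuple(
                lbl for member in g.member_labels for lbl in image_labels[member]
            ),
        )
        for g in structure.groups.values()
    }
    return CrystalStructure(
        cell=structure.cell,
        sites=new_sites,
        symmetry_ops=[SymOp.identity()],
        groups=new_groups,
    )


class DistanceEntry(NamedTuple):
    label_j: str
    label_k: str
    image: tuple[int, int, int]
    r_pm: float


@dataclass(frozen=True)
class DistanceList:
    """All contacts between two site groups within a cutoff, sorted by r.

    For a homonuclear self-pair (``group_j == group_k``) each unordered
    atom pair appears once and the zero-distance self-contact is excluded.
    """

    pair: tuple[str, str]
    species: tuple[str, str]
    entries: tuple[DistanceEntry, ...]
    cutoff_pm: float

    @property
    def r(self) -> np.ndarray:
        """Distances in pm, ascending."""
        return np.array([e.r_pm for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def truncated(self, m: int) -> "DistanceList":
        if not 1 <= m <= len(self.entries):
            raise ValueError(f"multiplicity {m} outside 1..{len(self.entries)}")
        return replace(self, entries=self.entries[:m])


def _image_shell(cell: UnitCell, cutoff_angstrom: float) -> np.ndarray:
    """Integer lattice translations whose shell covers the cutoff sphere."""
    mat = cell.matrix
    vol = cell.volume
    counts = []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        face = np.linalg.norm(np.cross(mat[:, j], mat[:, k]))
        spacing = vol / face  # perpendicular distance between lattice planes
        counts.append(int(math.ceil(cutoff_angstrom / spacing)) + 1)
    ranges = [np.arange(-n, n + 1) for n in counts]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


def enumerate_distances(
    structure: CrystalStructure,
    group_j: str,
    group_k: str,
    cutoff_pm: float = 1000.0,
) -> DistanceList:
    """Enumerate every atom-atom contact between two groups up to ``cutoff_pm``.

    The structure is auto-expanded to P1 if needed.  The returned list is
    sorted ascending in distance and includes all periodic images within
    the cutoff (intermolecular contacts included).
    """
    if cutoff_pm <= 0:
        raise ValueError("cutoff must be positive")
    if not structure.is_p1:
        structure = expand_to_p1(structure)
    gj = structure.group(group_j)
    gk = structure.group(group_k)
    cell = structure.cell
    cutoff_angstrom = cutoff_pm / ANGSTROM_TO_PM

    frac_by_label = {s.label: np.array(s.frac) for s in structure.sites}
    fj = np.array([frac_by_label[l] for l in gj.member_labels])
    fk = np.array([frac_by_label[l] for l in gk.member_labels])
    images = _image_shell(cell, cutoff_angstrom)

    mat = cell.matrix
    cart_j = fj @ mat.T  # (nj, 3)
    cart_k = fk @ mat.T  # (nk, 3)
    shifts = images @ mat.T  # (ni, 3)

    diff = cart_j[:, None, None, :] - (cart_k[None, :, None, :] + shifts[None, None, :, :])
    dist = np.linalg.norm(diff, axis=-1)  # (nj, nk, ni) in angstrom

    same_group = group_j == group_k
    nj, nk, ni = dist.shape
    mask = dist <= cutoff_angstrom + 1e-12
    if same_group:
        # count each unordered (atom, atom, image) contact once:
        # keep a<b over all images; for a==b keep the lexicographically
        # positive half-shell (t and -t give the same contact), drop t=0.
        aj = np.arange(nj)[:, None, None]
        bk = np.arange(nk)[None, :, None]
        lex_pos = (
            (images[:, 0] > 0)
            | ((images[:, 0] == 0) & (images[:, 1] > 0))
            | ((images[:, 0] == 0) & (images[:, 1] == 0) & (images[:, 2] > 0))
        )[None, None, :]
        mask &= (aj < bk) | ((aj == bk) & lex_pos)
    entries = [
        DistanceEntry(
            gj.member_labels[a],
            gk.member_labels[b],
            tuple(int(x) for x in images[i]),
            float(dist[a, b, i] * ANGSTROM_TO_PM),
        )
        for a, b, i in zip(*np.nonzero(mask))
    ]
    entries.sort(key=lambda e: (e.r_pm, e.label_j, e.label_k, e.image))
    if not entries:
        warnings.warn(
            f"no {group_j}-{group_k} contacts within {cutoff_pm:g} pm; "
            "cutoff may be shorter than the shortest relevant bond",
            stacklevel=2,
        )
    return DistanceList(
        pair=(group_j, group_k),
        species=(gj.species, gk.species),
        entries=tuple(entries),
        cutoff_pm=cutoff_pm,
    )
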