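"""Chemical-shift-tensor algebra in the Haeberlen convention.

Computed (GIPAW) principal *shieldings* sigma_aa convert to principal
*shifts* by delta_aa = sigma_ref - sigma_aa, with sigma_ref calibrated by
an offset-only regression against experimental isotropic shifts.  The
principal components are then relabelled by their deviation from the
isotropic average,

    |delta_zz - delta_iso| >= |delta_xx - delta_iso| >= |delta_yy - delta_iso|,

giving the anisotropy delta_aniso = delta_zz - delta_iso (sign included),
the asymmetry eta = (delta_yy - delta_xx) / delta_aniso in [0, 1], the
span Omega = |delta_zz - delta_xx|, and iota = delta_iso - delta_yy.  The
sign of iota always matches that of delta_aniso, which is what makes the
single signed anisotropy a sufficient diagnostic of, e.g., phosphate
protonation/coordination state.  The most common alternative convention
quotes an anisotropy larger by 3/2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShieldingTensor",
    "ShiftTensor",
    "SigmaRef",
    "shielding_to_shift",
    "haeberlen_params",
    "convert_convention",
    "fit_sigma_ref",
    "motional_average_shifts",
    "read_tensor_table",
    "read_magres",
]

#: Relative tolerance below which a tensor counts as isotropic.
ISO_TOL = 1e-12


@dataclass(frozen=True)
class ShieldingTensor:
    """Principal shielding values (ppm) of one site."""

    site_id: str
    species: str
    sigma: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(not math.isfinite(s) for s in self.sigma):
            raise ValueError(f"site {self.site_id!r}: non-finite shielding values")


@dataclass(frozen=True)
class ShiftTensor:
    """Haeberlen-ordered principal shifts (ppm) with derived scalars.

    ``delta`` is ordered (delta_xx, delta_yy, delta_zz) after relabelling.
    For an isotropic tensor eta is reported as 0.0 with ``isotropic=True``
    rather than NaN.
    """

    site_id: str
    species: str
    delta: tuple[float, float, float]
    delta_iso: float
    delta_aniso: float
    eta: float
    span: float
    iota: float
    isotropic: bool = False


def haeberlen_params(
    values: Sequence[float], site_id: str = "", species: str = ""
) -> ShiftTensor:
    """Relabel a principal-shift triple and derive the Haeberlen scalars.

    Components are assigned by descending deviation from the isotropic
    average (zz = largest, then xx, then yy).  Exact ties (axially
    symmetric tensors) are broken by a stable sort on the input order, so
    the unique component of an axial tensor lands on zz and eta = 0.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != (3,) or not np.all(np.isfinite(vals)):
        raise ValueError("need three finite principal values")
    iso = float(vals.mean())
    dev = vals - iso
    scale = float(np.abs(vals).max()) or 1.0
    if np.abs(dev).max() <= ISO_TOL * scale:
        return ShiftTensor(site_id, species, (iso, iso, iso), iso, 0.0, 0.0, 0.0, 0.0, True)
    order = np.argsort(-np.abs(dev), kind="stable")  # [zz, xx, yy]
    dzz, dxx, dyy = (float(vals[i]) for i in order)
    aniso = dzz - iso
    eta = (dyy - dxx) / aniso
    return ShiftTensor(
        site_id=site_id,
        species=species,
        delta=(dxx, dyy, dzz),
        delta_iso=iso,
        delta_aniso=aniso,
        eta=float(eta),
        span=abs(dzz - dxx),
        iota=iso - dyy,
    )


@dataclass(frozen=True)
class SigmaRef:
    """Shielding-to-shift conversion offset for one species, with fit diagnostics."""

    species: str
    sigma_ref: float
    r_squared: float
    residuals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must lie in [0, 1]")


def shielding_to_shift(tensor: ShieldingTensor, sigma_ref: float | SigmaRef) -> ShiftTensor:
    """Convert principal shieldings to Haeberlen-ordered principal shifts.

    delta_aa = sigma_ref - sigma_aa component-wise; a shift of sigma_ref
    moves delta_iso rigidly and leaves delta_aniso and eta unchanged.
    """
    ref = sigma_ref.sigma_ref if isinstance(sigma_ref, SigmaRef) else float(sigma_ref)
    delta = tuple(ref - s for s in tensor.sigma)
    return haeberlen_params(delta, site_id=tensor.site_id, species=tensor.species)


def convert_convention(delta_aniso_haeberlen: float, inverse: bool = False) -> float:
    """Interconvert the anisotropy with the common 3/2-larger convention."""
    factor = 2.0 / 3.0 if inverse else 1.5
    return delta_aniso_haeberlen * factor


def fit_sigma_ref(
    pairs: Sequence[tuple[float, float]], species: str = ""
) -> SigmaRef:
    """Calibrate sigma_ref from (sigma_iso_calc, delta_iso_exp) pairs.

    Offset-only least squares with the slope fixed at -1 (the conversion
    delta = sigma_ref - sigma admits no free slope):
    sigma_ref = mean(delta_exp + sigma_calc).  R^2 is the squared Pearson
    correlation of predicted vs. experimental shifts; with fewer than two
    points, or zero variance, the fit is exact by construction and R^2 is
    reported as 1.
    """
    if not pairs:
        raise ValueError("need at least one (sigma_calc, delta_exp) pair")
    sigma = np.array([p[0] for p in pairs], dtype=float)
    delta = np.array([p[1] for p in pairs], dtype=float)
    ref = float(np.mean(delta + sigma))
    predicted = ref - sigma
    residuals = delta - predicted
    if len(pairs) < 2 or np.std(delta) == 0 or np.std(predicted) == 0:
        r2 = 1.0
    else:
        r2 = float(np.corrcoef(predicted, delta)[0, 1] ** 2)
    return SigmaRef(
        species=species,
        sigma_ref=ref,
        r_squared=min(max(r2, 0.0), 1.0),
        residuals=tuple(float(x) for x in residuals),
    )


def motional_average_shifts(member_shifts: Iterable[float]) -> float:
    """Arithmetic mean shift of crystallographically inequivalent sites
    rendered equivalent by fast motion (NH3 rotors, water)."""
    shifts = list(member_shifts)
    if not shifts:
        raise ValueError("need at least one member shift")
    return float(np.mean(shifts))


def read_tensor_table(path: str, sep: str = "\t") -> list[ShieldingTensor]:
    """Read a delimited table with columns site, species, sigma_xx, sigma_yy, sigma_zz."""
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"site", "species", "sigma_xx", "sigma_yy", "sigma_zz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ShieldingTensor(
            site_id=str(row.site),
            species=str(row.species),
            sigma=(float(row.sigma_xx), float(row.sigma_yy), float(row.sigma_zz)),
        )
        for row in df.itertuples(index=False)
    ]


_MAGRES_SPECIES = {"H": "1H", "C": "13C", "P": "31P", "N": "15N", "F": "19F", "Si": "29Si"}


def read_magres(path: str) -> list[ShieldingTensor]:
    """Read magnetic-shielding tensors from a magres-format text file.

    Parses ``ms`` lines of the ``[magres]`` block (element, index, nine
    tensor components, row-major); principal values are the eigenvalues of
    the symmetrized tensor.
    """
    tensors: list[ShieldingTensor] = []
    in_block = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if re.fullmatch(r"\[magres\]", stripped):
                in_block = True
                continue
            if re.fullmatch(r"\[/magres\]", stripped):
                in_block = False
                continue
            if not in_block or not stripped.startswith("ms "):
                continue
            parts = stripped.split()
            if len(parts) != 12:
                raise ValueError(f"{path}: malformed ms line: {stripped!r}")
            element, index = parts[1], parts[2]
            mat = np.array([float(x) for x in parts[3:]]).reshape(3, 3)
            sym = 0.5 * (mat + mat.T)
            eigvals = np.linalg.eigvalsh(sym)
            tensors.append(
                ShieldingTensor(
                    site_id=f"{element}{index}",
                    species=_MAGRES_SPECIES.get(element, element),
                    sigma=tuple(float(v) for v in eigvals),
                )
            )
    if not tensors:
        raise ValueError(f"{path}: no ms records found in a [magres] block")
    return tensors
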