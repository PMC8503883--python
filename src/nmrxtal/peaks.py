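"""From integrated 2D NMR peak intensities to effective distances.

In the quantitative regime (very short recoupling / CP contact time) the
integrated intensity of each 2D correlation peak class is proportional to
the squared effective dipolar coupling of that site pair.  The fractional
intensity f_NMR = I / I_tot therefore equals the pair's fractional dipolar
contact, and anchoring the total to a reference structure model via
I_tot = b_tot^2(model) converts the measured fractions into experimental
effective couplings and distances:

    b_eff^2_NMR(j,k) = f_NMR(j,k) * b_tot^2(model)
    r_eff_NMR(j,k)   = r_eff_model(j,k) * (f_model / f_NMR)^(1/6)

The second identity is exact and independent of the dipolar constant and
multiplicity; it is asserted internally.  First-order propagation of
r ~ f^(-1/6) gives sigma_rel(r) = sigma_rel(f) / 6.

Conventions for homonuclear 2Q-1Q data: a cross peak of two inequivalent
sites is the SUM of its two symmetric 2D peaks; an autocorrelation
(diagonal) peak of an equivalent pair is a single peak.  Peak picking and
deconvolution are out of scope — this module consumes integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dipolar import ContactSet, EffectiveCoupling, effective_distance

__all__ = [
    "PeakRecord",
    "PeakTable",
    "DistanceReport",
    "read_peak_table",
    "fractional_contacts_nmr",
    "distances_from_intensities",
    "propagate_uncertainty",
    "quantitativity_check",
]

Pair = tuple[str, str]

PEAK_KINDS = ("heteronuclear", "2Q-cross", "2Q-autocorrelation")


@dataclass(frozen=True)
class PeakRecord:
    """One integrated 2D NMR peak-intensity entry for a site-pair class."""

    pair: Pair
    intensity: float
    kind: str = "heteronuclear"
    sigma_rel: float = 0.0
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"pair {self.pair}: intensity must be >= 0")
        if self.kind not in PEAK_KINDS:
            raise ValueError(f"pair {self.pair}: unknown peak kind {self.kind!r}")
        if self.sigma_rel < 0:
            raise ValueError(f"pair {self.pair}: sigma_rel must be >= 0")


@dataclass
class PeakTable:
    """Integrated peak intensities, optionally with a whole-spectrum total.

    ``i_tot`` defaults to the sum of included, assigned intensities (so the
    fractions sum to one); pass the whole-spectrum integral explicitly when
    unassigned signal exists.
    """

    records: list[PeakRecord]
    i_tot: float | None = None

    def __post_init__(self) -> None:
        pairs = [r.pair for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pair in peak table")
        included = self.included_sum
        if self.i_tot is not None and self.i_tot < included - 1e-9 * max(included, 1.0):
            raise ValueError("i_tot cannot be smaller than the included intensity sum")

    @property
    def included(self) -> list[PeakRecord]:
        return [r for r in self.records if not r.excluded]

    @property
    def included_sum(self) -> float:
        return float(sum(r.intensity for r in self.included))


def read_peak_table(path: str, sep: str = "\t") -> PeakTable:
    """Read a delimited peak table.

    Required columns: ``group_j``, ``group_k``, ``intensity``.  Optional:
    ``kind``, ``sigma_rel``, ``excluded``, ``reason``.  An intensity of
    ``n.d.`` (or empty) marks the pair excluded as not determined.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str).fillna("")
    required = {"group_j", "group_k", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        raw_i = str(row.intensity).strip()
        not_determined = raw_i in ("", "n.d.", "nd", "NA")
        excluded = str(getattr(row, "excluded", "")).strip().lower() in ("1", "true", "yes")
        reason = str(getattr(row, "reason", "")).strip()
        if not_determined:
            excluded, reason = True, reason or "n.d."
        records.append(
            PeakRecord(
                pair=(str(row.group_j).strip(), str(row.group_k).strip()),
                intensity=0.0 if not_determined else float(raw_i),
                kind=str(getattr(row, "kind", "heteronuclear")).strip() or "heteronuclear",
                sigma_rel=float(str(getattr(row, "sigma_rel", "0")).strip() or 0.0),
                excluded=excluded,
                reason=reason,
            )
        )
    return PeakTable(records=records)


@dataclass(frozen=True)
class FractionSet:
    """Raw (vs. i_tot) and renormalized (included-sum) fractional intensities."""

    raw: dict[Pair, float]
    renormalized: dict[Pair, float]
    excluded: dict[Pair, str]
    sigma_rel: dict[Pair, float]


def fractional_contacts_nmr(table: PeakTable) -> FractionSet:
    """Fractional intensities f_NMR = I / I_tot per pair class.

    Excluded records (not determined, outliers) are dropped and the
    remaining fractions renormalized to unit sum; both the raw and the
    renormalized values are reported.
    """
    included = table.included
    if not included:
        raise ValueError("no included peak records")
    inc_sum = table.included_sum
    i_tot = table.i_tot if table.i_tot is not None else inc_sum
    if i_tot <= 0 or inc_sum <= 0:
        raise ValueError("total integrated intensity must be positive")
    raw = {r.pair: r.intensity / i_tot for r in included}
    renorm = {r.pair: r.intensity / inc_sum for r in included}
    return FractionSet(
        raw=raw,
        renormalized=renorm,
        excluded={r.pair: r.reason or "excluded" for r in table.records if r.excluded},
        sigma_rel={r.pair: r.sigma_rel for r in included},
    )


def propagate_uncertainty(sigma_rel_f: float) -> float:
    """First-order propagation of r ~ f^(-1/6): sigma_rel(r) = sigma_rel(f)/6."""
    if sigma_rel_f < 0:
        raise ValueError("relative uncertainty must be >= 0")
    return sigma_rel_f / 6.0


@dataclass
class DistanceReport:
    """NMR-derived contacts and effective distances against one reference model."""

    reference_id: str
    frame: pd.DataFrame = field(repr=False)

    def r_eff_nmr(self) -> dict[Pair, float]:
        return {
            (row.group_j, row.group_k): row.r_eff_nmr_pm
            for row in self.frame.itertuples(index=False)
        }


def distances_from_intensities(
    f_nmr: Mapping[Pair, float],
    reference: ContactSet,
    sigma_rel_f: Mapping[Pair, float] | None = None,
    reference_id: str = "model",
) -> DistanceReport:
    """Convert fractional NMR intensities into effective distances.

    The reference model supplies b_tot^2 and the per-pair multiplicity and
    motional scale.  Every pair in ``f_nmr`` must exist in the reference.
    """
    missing = [p for p in f_nmr if p not in reference.couplings]
    if missing:
        raise KeyError(f"pairs missing from reference model: {missing}")
    sigma_rel_f = dict(sigma_rel_f or {})
    b_tot = reference.b_tot_sq
    f_model = reference.f_model
    rows = []
    for pair, f in f_nmr.items():
        if f <= 0:
            raise ValueError(f"pair {pair}: f_NMR must be positive")
        ref = reference.couplings[pair]
        b_sq_nmr = f * b_tot
        nmr_eff = EffectiveCoupling(
            pair=pair,
            species=ref.species,
            m_pair=ref.m_pair,
            b_eff_sq=b_sq_nmr,
            scale=ref.scale,
        )
        r_nmr = effective_distance(nmr_eff)
        r_model = effective_distance(ref)
        if pair in f_model:  # exact ratio identity, independent of M and K
            assert math.isclose(
                r_nmr, r_model * (f_model[pair] / f) ** (1.0 / 6.0), rel_tol=1e-9
            )
        s_f = sigma_rel_f.get(pair, 0.0)
        rows.append(
            {
                "group_j": pair[0],
                "group_k": pair[1],
                "f_nmr": f,
                "f_model": f_model.get(pair, np.nan),
                "b_eff_sq_nmr": b_sq_nmr,
                "r_eff_nmr_pm": r_nmr,
                "r_eff_model_pm": r_model,
                "delta_r_pm": r_nmr - r_model,
                "sigma_rel_f": s_f,
                "sigma_rel_r": propagate_uncertainty(s_f),
            }
        )
    return DistanceReport(reference_id=reference_id, frame=pd.DataFrame(rows))


def quantitativity_check(
    buildup: Sequence[tuple[float, float]],
    analysis_time: float,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Diagnostic for the quantitative-regime prerequisite.

    The distance mapping assumes the analysis point sits early on the
    intensity-buildup curve, I/I_max -> 0; in practice a ratio comfortably
    below ~0.5 keeps the 2Q-1Q analysis quantitative.  Returns
    ``(ratio, ok)`` where ``ok`` is False (warn) when the ratio at the
    analysis time exceeds ``threshold``.
    """
    if len(buildup) < 2:
        raise ValueError("need at least two buildup points")
    times = np.array([t for t, _ in buildup], dtype=float)
    intensities = np.array([i for _, i in buildup], dtype=float)
    sel = np.isclose(times, analysis_time, rtol=1e-9, atol=1e-15)
    if not sel.any():
        raise ValueError(f"analysis time {analysis_time} not in the buildup series")
    i_max = float(intensities.max())
    if i_max <= 0:
        raise ValueError("buildup series has no positive intensity")
    ratio = float(intensities[sel][0] / i_max)
    return ratio, ratio <= threshold
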