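"""Screening of candidate crystal structures against NMR-derived distances.

The screening protocol: (1) measure one quantitative 2D spectrum, (2) form
fractional peak intensities, (3) compute the model-side fractional dipolar
contacts of each candidate structure, (4) compare the NMR-derived and
model effective distances (or the fractions directly) and rank the
candidates.  Because step (3) is a cheap lattice sum, very large candidate
pools can be screened.

R^2 here is the squared Pearson correlation between the two distance sets;
it is insensitive to a systematic offset, so the default ranking key is
the rmsd of the per-pair distance deviations (both are always reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .crystal import CrystalStructure
from .dipolar import fractional_contacts_model
from .peaks import FractionSet, distances_from_intensities

__all__ = ["ComparisonReport", "compare_distances", "shift_rmsd", "rank_models"]

Pair = tuple[str, str]


@dataclass
class ComparisonReport:
    """Per-pair distance deviations and summary statistics for one model."""

    model_id: str
    frame: pd.DataFrame = field(repr=False)  # pair, r_nmr, r_model, delta_r
    rmsd_pm: float
    r_squared: float | None
    dropped_pairs: list[Pair] = field(default_factory=list)
    failed: bool = False
    message: str = ""


def compare_distances(
    nmr: Mapping[Pair, float],
    model: Mapping[Pair, float],
    model_id: str = "model",
) -> ComparisonReport:
    """Compare two effective-distance sets pair-by-pair.

    delta_r = r_NMR - r_model per common pair; rmsd over the deviations;
    R^2 (squared Pearson) when >= 2 common pairs, else omitted with a
    notice.  Pairs present in only one set are dropped from the statistics
    and listed.  The report is sorted by |delta_r| descending.
    """
    common = [p for p in nmr if p in model]
    dropped = [p for p in nmr if p not in model] + [p for p in model if p not in nmr]
    if not common:
        raise ValueError("no common pairs between the two distance sets")
    r_nmr = np.array([nmr[p] for p in common])
    r_model = np.array([model[p] for p in common])
    delta = r_nmr - r_model
    rmsd = float(np.sqrt(np.mean(delta**2)))
    r2: float | None
    if len(common) >= 2 and np.std(r_nmr) > 0 and np.std(r_model) > 0:
        r2 = float(np.corrcoef(r_nmr, r_model)[0, 1] ** 2)
    else:
        r2 = None
    frame = pd.DataFrame(
        {
            "group_j": [p[0] for p in common],
            "group_k": [p[1] for p in common],
            "r_nmr_pm": r_nmr,
            "r_model_pm": r_model,
            "delta_r_pm": delta,
        }
    ).sort_values("delta_r_pm", key=np.abs, ascending=False, ignore_index=True)
    message = "" if r2 is not None else "R^2 omitted: fewer than 2 common pairs or zero variance"
    return ComparisonReport(
        model_id=model_id,
        frame=frame,
        rmsd_pm=rmsd,
        r_squared=r2,
        dropped_pairs=dropped,
        message=message,
    )


def shift_rmsd(pairs: Sequence[tuple[float, float]]) -> float:
    """Root-mean-square deviation (ppm) between experimental and computed
    isotropic shifts, from (delta_exp, delta_calc) pairs."""
    if not pairs:
        raise ValueError("need at least one shift pair")
    arr = np.asarray(pairs, dtype=float)
    return float(np.sqrt(np.mean((arr[:, 0] - arr[:, 1]) ** 2)))


def rank_models(
    fractions: FractionSet,
    candidates: Iterable[tuple[str, CrystalStructure]],
    pairs: Sequence[Pair],
    cutoff_pm: float = 1000.0,
    multiplicity: Mapping[Pair, int] | None = None,
    motional_scales: Mapping[Pair, float] | None = None,
    key: str = "rmsd",
) -> list[ComparisonReport]:
    """Score every candidate structure against one set of NMR fractions.

    Each candidate's fractional contacts anchor the same measured
    fractions, yielding per-candidate NMR/model effective-distance pairs.
    Ordering key: ``"rmsd"`` (default, ascending) or ``"r2"`` (descending);
    deterministic tie-break by model id.  A candidate whose contact
    computation fails is reported as failed and ranked last.
    """
    if key not in ("rmsd", "r2"):
        raise ValueError("ranking key must be 'rmsd' or 'r2'")
    reports: list[ComparisonReport] = []
    f_nmr = fractions.renormalized
    for model_id, structure in candidates:
        try:
            contacts = fractional_contacts_model(
                structure,
                pairs,
                cutoff_pm=cutoff_pm,
                multiplicity=multiplicity,
                motional_scales=motional_scales,
            )
            usable = {p: f for p, f in f_nmr.items() if p in contacts.couplings}
            report_in = distances_from_intensities(usable, contacts, reference_id=model_id)
            reports.append(
                compare_distances(
                    report_in.r_eff_nmr(),
                    {p: contacts.r_eff_model[p] for p in usable},
                    model_id=model_id,
                )
            )
        except Exception as exc:
            reports.append(
                ComparisonReport(
                    model_id=model_id,
                    frame=pd.DataFrame(),
                    rmsd_pm=float("inf"),
                    r_squared=None,
                    failed=True,
                    message=f"contact computation failed: {exc}",
                )
            )
    if key == "rmsd":
        reports.sort(key=lambda r: (r.failed, r.rmsd_pm, r.model_id))
    else:
        reports.sort(
            key=lambda r: (r.failed, -(r.r_squared if r.r_squared is not None else -1.0), r.model_id)
        )
    return reports
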