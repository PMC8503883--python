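"""Declarative analysis configuration.

A YAML document names the site groups (group id -> atom labels + spin
species), the pair classes to analyse, dipolar multiplicities, motional
groups/scales, exclusions, and the lattice-sum cutoff:

.. code-block:: yaml

    groups:
      P:    {species: "31P", atoms: [P1]}
      NH3:  {species: "1H", atoms: [H1, H2, H3], equivalent_by_motion: true,
             motional_scale: 0.5}
    pairs:
      - [P, NH3]
    multiplicity:
      - {pair: [P, NH3], m: 3}
    motional_scales:
      - {pair: [NH3, NH3], scale: 0.5}
    exclude:
      - {pair: [CH, CH], reason: outlier}
    cutoff_pm: 1000
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .crystal import SiteGroup

__all__ = ["AnalysisConfig", "load_config"]

Pair = tuple[str, str]


@dataclass
class AnalysisConfig:
    """Site groups and analysis parameters for one structure evaluation."""

    groups: list[SiteGroup]
    pairs: list[Pair]
    cutoff_pm: float = 1000.0
    multiplicity: dict[Pair, int] = field(default_factory=dict)
    motional_scales: dict[Pair, float] = field(default_factory=dict)
    exclude: dict[Pair, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cutoff_pm <= 0:
            raise ValueError("cutoff_pm must be positive")
        known = {g.id for g in self.groups}
        for pair in self.pairs:
            unknown = set(pair) - known
            if unknown:
                raise ValueError(f"pair {pair} references unknown groups {sorted(unknown)}")


def _as_pair(value: object) -> Pair:
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise ValueError(f"expected a [group_j, group_k] pair, got {value!r}")
    return (str(value[0]), str(value[1]))


def load_config(path: str) -> AnalysisConfig:
    """Parse a YAML analysis configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValueError(f"{path}: config must be a mapping with a 'groups' section")
    groups = [
        SiteGroup(
            id=str(gid),
            member_labels=tuple(str(a) for a in spec["atoms"]),
            species=str(spec["species"]),
            equivalent_by_motion=bool(spec.get("equivalent_by_motion", False)),
            motional_scale=float(spec.get("motional_scale", 1.0)),
        )
        for gid, spec in doc["groups"].items()
    ]
    pairs = [_as_pair(p) for p in doc.get("pairs", [])]
    if not pairs:
        raise ValueError(f"{path}: config lists no pair classes")
    return AnalysisConfig(
        groups=groups,
        pairs=pairs,
        cutoff_pm=float(doc.get("cutoff_pm", 1000.0)),
        multiplicity={_as_pair(e["pair"]): int(e["m"]) for e in doc.get("multiplicity", [])},
        motional_scales={
            _as_pair(e["pair"]): float(e["scale"]) for e in doc.get("motional_scales", [])
        },
        exclude={
            _as_pair(e["pair"]): str(e.get("reason", "excluded"))
            for e in doc.get("exclude", [])
        },
    )
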