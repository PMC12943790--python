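"""Packaged case studies and a generator of synthetic ideal systems.

Three fully worked resolution systems ship with the package (two
chloromandelic-acid/cyclohexylethylamine systems blocked by a double salt,
and the chloromandelic-acid/pregabalin system with a 50 K salt-pair
melting gap), plus two literature reference fixtures, one metrics-only and
one topology-only.  ``generate_synthetic_system`` produces random but
structurally canonical ideal-eutectic systems for property testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .phases import CrystallinePhase, Role
from .ternary import TernaryDiagram, assemble

__all__ = ["CaseStudy", "available_cases", "load_case", "generate_synthetic_system"]

_DATA_PACKAGE = "saltscreen.data"


@dataclass
class CaseStudy:
    """A named phase table with its sub-ternary topology and side data."""

    label: str
    description: str
    base_components: tuple[str, str, str]
    phases: list[CrystallinePhase]
    explicit_triplets: list[list[str]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def phase(self, name: str) -> CrystallinePhase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(
            f"unknown phase {name!r}; available: {[p.name for p in self.phases]}"
        )

    def diagram(self, compute_eutectics: bool = True) -> TernaryDiagram:
        """Assemble the ternary diagram using the case's sub-ternary triplets."""
        return assemble(
            self.phases,
            base_components=self.base_components,
            explicit_triplets=self.explicit_triplets or None,
            compute_eutectics=compute_eutectics,
        )


def available_cases() -> list[str]:
    files = resources.files(_DATA_PACKAGE)
    return sorted(
        f.name.removesuffix(".json")
        for f in files.iterdir()
        if f.name.endswith(".json")
    )


def load_case(label: str) -> CaseStudy:
    """Load a packaged case study by label.

    Unknown labels raise ``KeyError`` listing the available cases.
    """
    files = resources.files(_DATA_PACKAGE)
    try:
        raw = json.loads(files.joinpath(f"{label}.json").read_text())
    except FileNotFoundError:
        raise KeyError(
            f"unknown case {label!r}; available: {available_cases()}"
        ) from None
    return CaseStudy(
        label=raw["label"],
        description=raw.get("description", ""),
        base_components=tuple(raw["base_components"]),
        phases=[CrystallinePhase.from_record(r) for r in raw["phases"]],
        explicit_triplets=[list(t) for t in raw.get("explicit_triplets", [])],
        extras=raw.get("extras", {}),
    )


def generate_synthetic_system(
    seed: int,
    n_salts: int = 2,
    t_fus_range: tuple[float, float] = (330.0, 470.0),
    dh_range: tuple[float, float] = (15000.0, 70000.0),
    with_double_salt: bool = False,
    with_racemic_compound: bool = True,
) -> CaseStudy:
    """A random ideal-eutectic resolution system with canonical topology.

    The phase set emulates the structure of the packaged cases: an
    enantiomer pair with identical melting data at the lower corners, a
    crystalline resolving agent at the apex, one or two 1:1 diastereomeric
    salts at the edge midpoints, optionally a racemic compound at
    (0.5, 0.5, 0) and a double salt at (0.25, 0.25, 0.5).  Melting points
    are drawn uniformly from ``t_fus_range`` (kelvin) and fusion enthalpies
    from ``dh_range`` (J/mol); the 1:1 addition compounds (racemic compound,
    double salt) draw their enthalpy from the upper half of the range,
    mirroring the empirical pattern that such compounds melt with roughly
    twice the enthalpy of the single components.  Deterministic in ``seed``.
    """
    t_lo, t_hi = t_fus_range
    dh_lo, dh_hi = dh_range
    if not (250.0 <= t_lo < t_hi <= 600.0):
        raise ValueError("t_fus_range must be an increasing interval within [250, 600] K")
    if not (0.0 < dh_lo < dh_hi):
        raise ValueError("dh_range must be a positive increasing interval")
    if n_salts not in (1, 2):
        raise ValueError("n_salts must be 1 (single salt) or 2 (salt pair)")

    rng = np.random.default_rng(seed)
    draw_t = lambda: float(rng.uniform(t_lo, t_hi))
    draw_dh = lambda: float(rng.uniform(dh_lo, dh_hi))
    draw_dh_compound = lambda: float(rng.uniform((dh_lo + dh_hi) / 2, dh_hi))

    t_en, dh_en = draw_t(), draw_dh()
    phases = [
        CrystallinePhase("E1", Role.ENANTIOMER, (1.0, 0.0, 0.0), t_en, dh_en),
        CrystallinePhase("E2", Role.ENANTIOMER, (0.0, 1.0, 0.0), t_en, dh_en),
        CrystallinePhase("G", Role.RESOLVING_AGENT, (0.0, 0.0, 1.0), draw_t(), draw_dh()),
        CrystallinePhase(
            "S1", Role.DIASTEREOMERIC_SALT, (0.5, 0.0, 0.5), draw_t(), draw_dh()
        ),
    ]
    if n_salts == 2:
        phases.append(
            CrystallinePhase(
                "S2", Role.DIASTEREOMERIC_SALT, (0.0, 0.5, 0.5), draw_t(), draw_dh()
            )
        )
    if with_racemic_compound:
        phases.append(
            CrystallinePhase(
                "RC", Role.RACEMIC_COMPOUND, (0.5, 0.5, 0.0), draw_t(), draw_dh_compound()
            )
        )
    if with_double_salt:
        if n_salts != 2:
            raise ValueError("a double salt requires the full salt pair")
        phases.append(
            CrystallinePhase(
                "D", Role.DOUBLE_SALT, (0.25, 0.25, 0.5), draw_t(), draw_dh_compound()
            )
        )

    triplets: Optional[list[list[str]]] = None
    if with_racemic_compound:
        if n_salts == 1:
            triplets = [["E1", "RC", "S1"], ["RC", "S1", "G"], ["RC", "E2", "G"]]
        elif with_double_salt:
            triplets = [
                ["E1", "RC", "S1"],
                ["RC", "S1", "D"],
                ["RC", "D", "S2"],
                ["RC", "E2", "S2"],
                ["S1", "D", "G"],
                ["D", "S2", "G"],
            ]
        else:
            triplets = [
                ["E1", "RC", "S1"],
                ["RC", "S1", "S2"],
                ["RC", "E2", "S2"],
                ["S1", "S2", "G"],
            ]
    # without a racemic compound the topology is left to the automatic
    # triangulation (a conglomerate system has no canonical diagonal choice)

    return CaseStudy(
        label=f"synthetic-{seed}",
        description="seeded random ideal-eutectic resolution system",
        base_components=("enantiomer-1", "enantiomer-2", "resolving-agent"),
        phases=phases,
        explicit_triplets=triplets or [],
        extras={
            "seed": seed,
            "n_salts": n_salts,
            "with_double_salt": with_double_salt,
            "with_racemic_compound": with_racemic_compound,
        },
    )
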