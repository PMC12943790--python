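"""Crystalline-phase records and composition handling.

A resolution system lives on the ternary composition simplex spanned by the
two enantiomers to be separated and the chiral resolving agent.  Every solid
phase that can crystallize in the system — the pure enantiomers, a racemic
compound, the diastereomeric salt pair, a possible double salt — is described
by a :class:`CrystallinePhase`: its stoichiometric position in the simplex
(barycentric coordinates, mole fraction of molecules) and its DSC-measured
melting point and enthalpy of fusion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np

from .constants import ATOMIC_WEIGHTS, celsius_to_kelvin

__all__ = [
    "Role",
    "CrystallinePhase",
    "Composition",
    "FormulaError",
    "molar_mass_from_formula",
    "specific_to_molar_enthalpy",
    "molar_to_specific_enthalpy",
]

_COORD_TOL = 1e-9
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Role(str, Enum):
    """What a solid phase is, within the resolution system."""

    ENANTIOMER = "enantiomer"
    RACEMIC_COMPOUND = "racemic_compound"
    RESOLVING_AGENT = "resolving_agent"
    DIASTEREOMERIC_SALT = "diastereomeric_salt"
    DOUBLE_SALT = "double_salt"
    OTHER_SALT = "other_salt"


class FormulaError(ValueError):
    """Raised when a chemical formula cannot be interpreted."""


def molar_mass_from_formula(formula: str) -> float:
    """Molar mass (g/mol) of a Hill-notation formula such as ``C16H24ClNO5``.

    Element symbols are one capital letter optionally followed by one lower
    case letter, each with an optional integer count.  Unknown symbols raise
    :class:`FormulaError` naming the offending symbol.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty chemical formula")
    formula = formula.strip()
    mass = 0.0
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"cannot parse formula {formula!r} at position {pos}"
            )
        symbol, count = match.group(1), match.group(2)
        weight = ATOMIC_WEIGHTS.get(symbol)
        if weight is None:
            raise FormulaError(f"unknown element symbol {symbol!r} in {formula!r}")
        mass += weight * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return mass


def specific_to_molar_enthalpy(dh_specific: float, molar_mass: float) -> float:
    """Convert a specific enthalpy of fusion (J/g) to molar (J/mol)."""
    if dh_specific <= 0 or molar_mass <= 0:
        raise ValueError("specific enthalpy and molar mass must be positive")
    return dh_specific * molar_mass


def molar_to_specific_enthalpy(dh_molar: float, molar_mass: float) -> float:
    """Convert a molar enthalpy of fusion (J/mol) to specific (J/g)."""
    if dh_molar <= 0 or molar_mass <= 0:
        raise ValueError("molar enthalpy and molar mass must be positive")
    return dh_molar / molar_mass


def _validate_coords(coords: Iterable[float]) -> tuple[float, float, float]:
    c = tuple(float(v) for v in coords)
    if len(c) != 3:
        raise ValueError(f"coords must be a barycentric triple, got {c!r}")
    if any(v < -_COORD_TOL or v > 1 + _COORD_TOL for v in c):
        raise ValueError(f"coords components must lie in [0, 1]: {c!r}")
    if abs(sum(c) - 1.0) > _COORD_TOL:
        raise ValueError(f"coords must sum to 1 within {_COORD_TOL}: {c!r}")
    return c


@dataclass(frozen=True)
class Composition:
    """A point of the ternary composition simplex.

    Barycentric mole fractions over the three base components, ordered
    (enantiomer-1, enantiomer-2, resolving agent); non-negative, sum to one.
    """

    fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", _validate_coords(self.fractions))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def mirrored(self) -> "Composition":
        """The enantiomer-swapped (vertical-median mirror) composition."""
        a, b, c = self.fractions
        return Composition((b, a, c))

    def __iter__(self):
        return iter(self.fractions)


#: The conventional resolution starting mixture: racemate and resolving agent
#: in 1:1 molar ratio, i.e. 0.25 + 0.25 enantiomers and 0.5 agent.
TEST_COMPOSITION = Composition((0.25, 0.25, 0.5))


@dataclass(frozen=True)
class CrystallinePhase:
    """One solid crystalline phase of the resolution system.

    ``t_fus`` (kelvin) and ``dh_fus`` (J/mol) come from DSC; either may be
    ``None`` for a phase with no usable melting data (e.g. an amorphous salt),
    in which case the phase can still carry stoichiometric coordinates for
    topology purposes but is excluded from liquidus calculations.
    """

    name: str
    role: Role
    coords: tuple[float, float, float]
    t_fus: Optional[float] = None
    dh_fus: Optional[float] = None
    formula: Optional[str] = None
    molar_mass: Optional[float] = None
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("phase name must be non-empty")
        object.__setattr__(self, "role", Role(self.role))
        object.__setattr__(self, "coords", _validate_coords(self.coords))
        if self.t_fus is not None and self.t_fus <= 0:
            raise ValueError(f"phase {self.name}: t_fus must be > 0 K")
        if self.dh_fus is not None and self.dh_fus <= 0:
            raise ValueError(f"phase {self.name}: dh_fus must be > 0 J/mol")
        if self.formula is not None:
            computed = molar_mass_from_formula(self.formula)
            if self.molar_mass is None:
                object.__setattr__(self, "molar_mass", computed)
            elif abs(self.molar_mass - computed) > 0.1:
                raise ValueError(
                    f"phase {self.name}: molar_mass {self.molar_mass} g/mol "
                    f"disagrees with formula {self.formula} ({computed:.2f} g/mol)"
                )
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValueError(f"phase {self.name}: molar_mass must be > 0")

    @property
    def has_thermo(self) -> bool:
        """Whether both melting point and enthalpy of fusion are available."""
        return self.t_fus is not None and self.dh_fus is not None

    @classmethod
    def from_record(cls, record: dict) -> "CrystallinePhase":
        """Build a phase from a plain mapping (one row of a phase table).

        Handles the unit fields of the external table schema: ``t_fus_unit``
        of ``C`` or ``K`` and ``dh_fus_unit`` of ``J/mol`` or ``J/g`` (the
        latter requires a molar mass, possibly derived from the formula).
        """
        rec = dict(record)
        t_fus = rec.get("t_fus")
        if t_fus is not None:
            unit = str(rec.get("t_fus_unit", "K")).strip()
            if unit.upper() in ("C", "°C", "CELSIUS"):
                t_fus = celsius_to_kelvin(float(t_fus))
            elif unit.upper() in ("K", "KELVIN"):
                t_fus = float(t_fus)
            else:
                raise ValueError(f"unknown temperature unit {unit!r}")
        formula = rec.get("formula") or None
        molar_mass = rec.get("molar_mass")
        molar_mass = float(molar_mass) if molar_mass not in (None, "") else None
        dh_fus = rec.get("dh_fus")
        if dh_fus is not None:
            unit = str(rec.get("dh_fus_unit", "J/mol")).strip().lower()
            if unit == "j/g":
                mm = molar_mass
                if mm is None and formula is not None:
                    mm = molar_mass_from_formula(formula)
                if mm is None:
                    raise ValueError(
                        f"phase {rec.get('name')!r}: specific enthalpy (J/g) "
                        "requires a molar mass or formula"
                    )
                dh_fus = specific_to_molar_enthalpy(float(dh_fus), mm)
            elif unit == "j/mol":
                dh_fus = float(dh_fus)
            else:
                raise ValueError(f"unknown enthalpy unit {unit!r}")
        coords = rec.get("coords")
        if coords is None:
            coords = (rec["coord1"], rec["coord2"], rec["coord3"])
        return cls(
            name=str(rec["name"]),
            role=Role(rec["role"]),
            coords=tuple(coords),
            t_fus=t_fus,
            dh_fus=dh_fus,
            formula=formula,
            molar_mass=molar_mass,
            provenance=rec.get("provenance", {}),
        )

    def to_record(self) -> dict:
        """Serializable mapping (kelvin / J/mol, the internal convention)."""
        return {
            "name": self.name,
            "role": self.role.value,
            "coords": list(self.coords),
            "t_fus": self.t_fus,
            "t_fus_unit": "K",
            "dh_fus": self.dh_fus,
            "dh_fus_unit": "J/mol",
            "formula": self.formula,
            "molar_mass": self.molar_mass,
        }
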