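"""Pseudo-binary melting phase diagrams solved from ideal liquidus branches.

A pseudo-binary section joins two end-member solids (two enantiomers, or the
two members of a diastereomeric salt pair), possibly with an intermediate
1:1 addition compound (a racemic compound, or a double salt) half-way along
it.  The section coordinate ``x`` is the mole fraction of the *first* end
member; an intermediate compound counts as 0.5 of each end member in this
bookkeeping, which is what lets its liquidus be written in Prigogine–Defay
form.

The diagram is the upper envelope of the branches: at a given composition the
equilibrium solid is the phase whose ideal liquidus temperature is highest.
Eutectic points are where adjacent branches intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .constants import R, kelvin_to_celsius
from .liquidus import (
    pd_T_at_fraction,
    svl_fraction_at_T,
    svl_T_at_fraction,
)
from .phases import CrystallinePhase

__all__ = [
    "EutecticPoint",
    "Branch",
    "BinaryDiagram",
    "NoEutecticError",
    "CompoundMetastableError",
    "solve_simple_eutectic",
    "solve_racemic_binary",
    "solve_compound_binary",
    "solve_pair_diagram",
]

#: Convergence target on the liquidus-fraction residual at a eutectic.
_X_TOL = 1e-8
_T_BRACKET_LOW = 1.0


class NoEutecticError(ValueError):
    """The two liquidus branches do not intersect within the section."""


class CompoundMetastableError(NoEutecticError):
    """The intermediate compound's branch never reaches the upper envelope."""


@dataclass(frozen=True)
class EutecticPoint:
    """Composition and temperature where two adjacent branches intersect."""

    x_A: float
    T_eu: float
    phases: tuple[str, str]
    degenerate: bool = False

    @property
    def T_eu_celsius(self) -> float:
        return kelvin_to_celsius(self.T_eu)


@dataclass(frozen=True)
class Branch:
    """One liquidus branch over its validity interval of the section."""

    phase: str
    kind: str  # "svl" or "pd"
    x_lo: float
    x_hi: float
    temperature: Callable[[float], float] = field(compare=False, repr=False)

    def covers(self, x: float, tol: float = 1e-12) -> bool:
        return self.x_lo - tol <= x <= self.x_hi + tol


@dataclass(frozen=True)
class BinaryDiagram:
    """A solved pseudo-binary section: branches plus eutectic point(s)."""

    phases: tuple[CrystallinePhase, ...]
    branches: tuple[Branch, ...]
    eutectics: tuple[EutecticPoint, ...]

    def liquidus(self, x: float) -> tuple[float, str]:
        """Upper-envelope liquidus temperature and owning phase at x ∈ [0,1]."""
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"section coordinate must lie in [0, 1], got {x}")
        best: Optional[tuple[float, str]] = None
        for br in self.branches:
            if not br.covers(x, tol=1e-9):
                continue
            try:
                t = br.temperature(x)
            except ValueError:
                continue
            if best is None or t > best[0]:
                best = (t, br.phase)
        if best is None:
            raise ValueError(f"no liquidus branch defined at x={x}")
        return best

    def sample(self, n: int = 201) -> dict:
        """Envelope samples on a uniform x grid, for export and plotting."""
        xs = np.linspace(0.0, 1.0, n)
        temps, owners = [], []
        for x in xs:
            # exact endpoints are the pure end members
            xq = min(max(x, 1e-12), 1 - 1e-12)
            t, p = self.liquidus(xq)
            temps.append(t)
            owners.append(p)
        temps = np.asarray(temps)
        return {
            "x": xs.tolist(),
            "T_K": temps.tolist(),
            "T_C": [kelvin_to_celsius(t) for t in temps],
            "phase": owners,
        }

    def to_json(self, n: int = 201) -> dict:
        return {
            "phases": [p.to_record() for p in self.phases],
            "eutectics": [
                {
                    "x_A": e.x_A,
                    "T_eu_K": e.T_eu,
                    "T_eu_C": e.T_eu_celsius,
                    "phases": list(e.phases),
                    "degenerate": e.degenerate,
                }
                for e in self.eutectics
            ],
            "samples": self.sample(n),
        }


def _upper_bracket(*phases: CrystallinePhase) -> float:
    return min(p.t_fus for p in phases) - 1e-6


def solve_simple_eutectic(
    phase_a: CrystallinePhase, phase_b: CrystallinePhase
) -> EutecticPoint:
    """Eutectic of two solids in ideal eutectic relation.

    Solves x_A(T) + x_B(T) = 1 with both fractions on their Schröder–van Laar
    branches; both fractions are monotone increasing in T, so the sum crosses
    1 at most once below the lower melting point.  Returns the eutectic with
    ``x_A`` the fraction of ``phase_a``.
    """
    if phase_a.name == phase_b.name:
        raise ValueError(f"identical phases ({phase_a.name!r}); no binary section")
    for p in (phase_a, phase_b):
        if not p.has_thermo:
            raise ValueError(f"phase {p.name!r} lacks melting data")
    if phase_a.t_fus == phase_b.t_fus and phase_a.dh_fus == phase_b.dh_fus:
        # coincident branches: the intersection is an interval; report its
        # symmetric midpoint and flag the degeneracy
        t_eu = svl_T_at_fraction(phase_a, 0.5)
        return EutecticPoint(
            x_A=0.5, T_eu=t_eu, phases=(phase_a.name, phase_b.name), degenerate=True
        )

    def residual(T: float) -> float:
        return (
            svl_fraction_at_T(phase_a, T) + svl_fraction_at_T(phase_b, T) - 1.0
        )

    hi = _upper_bracket(phase_a, phase_b)
    lo = _T_BRACKET_LOW
    if residual(hi) < 0 or residual(lo) > 0:
        raise NoEutecticError(
            f"liquidus branches of {phase_a.name!r} and {phase_b.name!r} "
            "do not sum to unity within the section"
        )
    t_eu = brentq(residual, lo, hi, xtol=1e-10, rtol=8.9e-16)
    x_a = svl_fraction_at_T(phase_a, t_eu)
    if abs(residual(t_eu)) > _X_TOL:
        raise NoEutecticError("eutectic solve failed to converge")
    if not 0.0 < x_a < 1.0:
        raise NoEutecticError(
            f"no eutectic within section for {phase_a.name!r}/{phase_b.name!r}"
        )
    return EutecticPoint(x_A=x_a, T_eu=t_eu, phases=(phase_a.name, phase_b.name))


def _side_eutectic(
    side: CrystallinePhase, compound: CrystallinePhase, n_scan: int = 4096
) -> tuple[float, float]:
    """Intersection of a side Schröder–van Laar branch with the compound's
    Prigogine–Defay branch.

    Returns (T_eu, x_side) with x_side the side phase's own liquidus
    fraction at the eutectic (in (0.5, 1) for a physically sensible system).
    The highest-temperature crossing is the physical eutectic: scanning
    descends from just below both melting points and refines the first sign
    change by bracketed root solving.
    """
    hi = min(side.t_fus, compound.t_fus) - 1e-6
    dh_c, t_c = compound.dh_fus, compound.t_fus

    def g(T: float) -> float:
        x = svl_fraction_at_T(side, T)
        if x >= 1.0 or x * (1.0 - x) == 0.0:
            return -np.inf
        return np.log(4.0 * x * (1.0 - x)) - dh_c / R * (1.0 / t_c - 1.0 / T)

    grid = np.linspace(hi, _T_BRACKET_LOW, n_scan)
    prev_t, prev_g = grid[0], g(grid[0])
    for t in grid[1:]:
        cur_g = g(t)
        if np.isfinite(prev_g) and np.isfinite(cur_g) and prev_g * cur_g <= 0:
            t_eu = brentq(g, t, prev_t, xtol=1e-10, rtol=8.9e-16)
            return t_eu, svl_fraction_at_T(side, t_eu)
        prev_t, prev_g = t, cur_g
    raise CompoundMetastableError(
        f"compound {compound.name!r} is everywhere metastable against "
        f"{side.name!r}: its liquidus branch never reaches the envelope"
    )


def _three_phase_section(
    end_a: CrystallinePhase,
    compound: CrystallinePhase,
    end_b: CrystallinePhase,
) -> BinaryDiagram:
    for p in (end_a, compound, end_b):
        if not p.has_thermo:
            raise ValueError(f"phase {p.name!r} lacks melting data")
    if len({end_a.name, compound.name, end_b.name}) != 3:
        raise ValueError("the three phases of a section must be distinct")
    mid = [(a + b) / 2 for a, b in zip(end_a.coords, end_b.coords)]
    if max(abs(m - c) for m, c in zip(mid, compound.coords)) > 1e-6:
        raise ValueError(
            f"compound {compound.name!r} must sit midway between "
            f"{end_a.name!r} and {end_b.name!r} on the section"
        )

    t_a, x_a = _side_eutectic(end_a, compound)  # x of A at the A-side eutectic
    t_b, x_b = _side_eutectic(end_b, compound)  # x of B at the B-side eutectic
    x_eu_right = x_a          # section coordinate of the A-side eutectic
    x_eu_left = 1.0 - x_b     # section coordinate of the B-side eutectic
    if not x_eu_left < x_eu_right:
        raise NoEutecticError(
            f"compound {compound.name!r} branch does not separate the two "
            "side branches; section topology is not a double eutectic"
        )

    branches = (
        Branch(
            phase=end_b.name,
            kind="svl",
            x_lo=0.0,
            x_hi=x_eu_left,
            temperature=lambda x, p=end_b: svl_T_at_fraction(p, 1.0 - x),
        ),
        Branch(
            phase=compound.name,
            kind="pd",
            x_lo=x_eu_left,
            x_hi=x_eu_right,
            temperature=lambda x, p=compound: pd_T_at_fraction(p, x),
        ),
        Branch(
            phase=end_a.name,
            kind="svl",
            x_lo=x_eu_right,
            x_hi=1.0,
            temperature=lambda x, p=end_a: svl_T_at_fraction(p, x),
        ),
    )
    eutectics = (
        EutecticPoint(x_A=x_eu_left, T_eu=t_b, phases=(end_b.name, compound.name)),
        EutecticPoint(x_A=x_eu_right, T_eu=t_a, phases=(compound.name, end_a.name)),
    )
    return BinaryDiagram(
        phases=(end_a, compound, end_b), branches=branches, eutectics=eutectics
    )


def solve_racemic_binary(
    enantiomer_a: CrystallinePhase,
    racemic_compound: CrystallinePhase,
    enantiomer_b: CrystallinePhase,
) -> BinaryDiagram:
    """Enantiomer–racemic-compound–enantiomer melting diagram.

    Three branches: Schröder–van Laar for each enantiomer near the pure ends
    and the Prigogine–Defay branch of the racemic compound in between, valid
    between the two eutectics.  For enantiomers with identical melting data
    the two eutectics are mirror images about x = 0.5.
    """
    return _three_phase_section(enantiomer_a, racemic_compound, enantiomer_b)


def solve_compound_binary(
    salt_a: CrystallinePhase,
    double_salt: CrystallinePhase,
    salt_b: CrystallinePhase,
) -> BinaryDiagram:
    """Salt–double-salt–salt section of a diastereomeric salt pair.

    The double salt plays the racemic compound's part on the salt–salt
    pseudo-binary axis: it counts as 0.5 of each salt in the section
    bookkeeping and its liquidus is written, formally, in Prigogine–Defay
    form.
    """
    return _three_phase_section(salt_a, double_salt, salt_b)


def solve_pair_diagram(
    phase_a: CrystallinePhase, phase_b: CrystallinePhase
) -> BinaryDiagram:
    """Full two-branch diagram of a simple eutectic pair."""
    eu = solve_simple_eutectic(phase_a, phase_b)
    branches = (
        Branch(
            phase=phase_b.name,
            kind="svl",
            x_lo=0.0,
            x_hi=eu.x_A,
            temperature=lambda x, p=phase_b: svl_T_at_fraction(p, 1.0 - x),
        ),
        Branch(
            phase=phase_a.name,
            kind="svl",
            x_lo=eu.x_A,
            x_hi=1.0,
            temperature=lambda x, p=phase_a: svl_T_at_fraction(p, x),
        ),
    )
    return BinaryDiagram(
        phases=(phase_a, phase_b), branches=branches, eutectics=(eu,)
    )
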