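"""Resolvability metrics and verdict rules for a resolution system.

The screening logic distilled from resolution practice:

* the eutectic composition x_eu of the diastereomeric salt pair estimates
  their eutonic (solubility) ratio, and caps the attainable efficiency via
  the Fogassy resolubility parameter F_max = 2 − 1/(1 − x_eu);
* an efficient resolution needs at least a 20 K gap between the salts'
  melting points (the higher-melting, less-soluble salt precipitates first);
* a double salt (addition compound of the two diastereomeric salts) that
  dominates at the 1:1 racemate:agent test composition blocks resolution —
  cooling there crystallizes the double salt, which contains both
  enantiomers in equal amounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .binary import NoEutecticError, solve_simple_eutectic
from .constants import kelvin_to_celsius
from .phases import TEST_COMPOSITION, Composition, CrystallinePhase, Role
from .ternary import TernaryDiagram

__all__ = [
    "fogassy_parameter",
    "salt_pair_metrics",
    "resolution_verdict",
    "recommended_mixing_segment",
    "ResolutionReport",
    "MELTING_GAP_THRESHOLD",
]

#: Minimum melting-point gap (K) of the salt pair for an efficient resolution.
MELTING_GAP_THRESHOLD = 20.0


def fogassy_parameter(x_eu: float) -> float:
    """Fogassy resolubility parameter F_max = 2 − 1/(1 − x_eu).

    ``x_eu`` is the mole fraction of the favored (higher-melting,
    less-soluble) salt at the salt pair's eutectic.  F_max is the theoretical
    maximum resolution efficiency: 1 at x_eu = 0, 0 at x_eu = 0.5, negative
    beyond (no thermodynamic preference left to exploit).
    """
    if not 0.0 <= x_eu < 1.0:
        raise ValueError(f"x_eu must lie in [0, 1), got {x_eu}")
    return 2.0 - 1.0 / (1.0 - x_eu)


def salt_pair_metrics(
    salt_a: CrystallinePhase, salt_b: CrystallinePhase
) -> tuple[float, float, float]:
    """(x_eu, ΔT_m, F_max) for a diastereomeric salt pair.

    x_eu is reported as the fraction of the HIGHER-melting salt at the
    pair's binary eutectic; ΔT_m is the absolute melting-point gap in
    kelvin.  Argument order does not matter.
    """
    for p in (salt_a, salt_b):
        if not p.has_thermo:
            raise ValueError(f"salt {p.name!r} lacks melting data")
    favored, other = (
        (salt_a, salt_b) if salt_a.t_fus >= salt_b.t_fus else (salt_b, salt_a)
    )
    eu = solve_simple_eutectic(favored, other)
    delta_tm = abs(salt_a.t_fus - salt_b.t_fus)
    return eu.x_A, delta_tm, fogassy_parameter(eu.x_A)


@dataclass
class ResolutionReport:
    """Outcome of screening one resolution system."""

    salt_pair: tuple[str, ...]
    verdict: str = "indeterminate"
    x_eu: Optional[float] = None
    f_max: Optional[float] = None
    delta_tm: Optional[float] = None
    test_point_phase: Optional[str] = None
    double_salt_present: bool = False
    favored_salt: Optional[str] = None
    mixing_segment: Optional[tuple[float, float]] = None
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "salt_pair": list(self.salt_pair),
            "verdict": self.verdict,
            "x_eu": self.x_eu,
            "f_max": self.f_max,
            "delta_tm_K": self.delta_tm,
            "test_point_phase": self.test_point_phase,
            "double_salt_present": self.double_salt_present,
            "favored_salt": self.favored_salt,
            "recommended_mixing_segment": (
                list(self.mixing_segment) if self.mixing_segment else None
            ),
            "notes": self.notes,
        }

    def summary(self) -> str:
        lines = [f"verdict: {self.verdict}"]
        if self.salt_pair:
            lines.append(f"diastereomeric salt pair: {', '.join(self.salt_pair)}")
        if self.delta_tm is not None:
            lines.append(f"melting-point gap: {self.delta_tm:.1f} K")
        if self.x_eu is not None:
            lines.append(
                f"eutectic fraction of favored salt ({self.favored_salt}): "
                f"x_eu = {self.x_eu:.3f}"
            )
        if self.f_max is not None:
            lines.append(f"Fogassy parameter F_max = {self.f_max:.3f}")
        if self.test_point_phase is not None:
            lines.append(
                "dominating solid at the 1:1 test composition: "
                f"{self.test_point_phase}"
            )
        if self.mixing_segment is not None:
            lo, hi = self.mixing_segment
            lines.append(
                "recommended racemate:agent mixing line segment "
                f"(agent fraction {lo:.3f}–{hi:.3f})"
            )
        lines.extend(f"note: {n}" for n in self.notes)
        return "\n".join(lines)


def recommended_mixing_segment(
    diagram: TernaryDiagram,
    favored_salt: str,
    n: int = 401,
) -> Optional[tuple[float, float]]:
    """Span of the racemate–agent mixing line inside the favored salt's domain.

    The mixing line runs from the racemic composition (0.5, 0.5, 0) to the
    pure resolving agent (0, 0, 1), parameterized by the agent mole fraction
    t ∈ [0, 1].  Returns the (t_lo, t_hi) interval over which the favored
    salt is the dominating solid, or ``None`` if the line never enters its
    domain.  Sampled at ``n`` points; only the widest contiguous run is
    reported.
    """
    ts = np.linspace(0.0, 1.0, n)
    inside = np.zeros(n, dtype=bool)
    for i, t in enumerate(ts):
        c = ((1 - t) / 2, (1 - t) / 2, t)
        try:
            _, name = diagram.liquidus_at(c)
        except ValueError:
            continue
        inside[i] = name == favored_salt
    if not inside.any():
        return None
    # widest contiguous run
    best_lo = best_hi = None
    run_lo = None
    for i, flag in enumerate(list(inside) + [False]):
        if flag and run_lo is None:
            run_lo = i
        elif not flag and run_lo is not None:
            if best_lo is None or (i - 1 - run_lo) > (best_hi - best_lo):
                best_lo, best_hi = run_lo, i - 1
            run_lo = None
    return (float(ts[best_lo]), float(ts[best_hi]))


def resolution_verdict(
    diagram: TernaryDiagram,
    report: Optional[ResolutionReport] = None,
    test_point: Composition = TEST_COMPOSITION,
) -> ResolutionReport:
    """Apply the verdict rules to an assembled ternary diagram.

    Order of the rules: a double salt dominating at the test composition
    blocks resolution outright; otherwise a melting-point gap of at least
    20 K between the diastereomeric salts is promising, a smaller gap
    inefficient.  Missing data (e.g. an amorphous salt with no fusion
    signal) degrades the verdict to indeterminate with an explanatory note.
    """
    salts = [p for p in diagram.phases if p.role == Role.DIASTEREOMERIC_SALT]
    double_salts = [p for p in diagram.phases if p.role == Role.DOUBLE_SALT]
    report = report or ResolutionReport(salt_pair=tuple(p.name for p in salts))
    report.salt_pair = tuple(p.name for p in salts)
    report.double_salt_present = bool(double_salts)

    try:
        t_test, dominating = diagram.liquidus_at(test_point)
        report.test_point_phase = dominating
        report.notes.append(
            f"dominating solid at 1:1 test point: {dominating} "
            f"(liquidus {kelvin_to_celsius(t_test):.1f} °C)"
        )
    except ValueError as exc:
        dominating = None
        report.notes.append(f"test point could not be evaluated: {exc}")

    salts_with_data = [p for p in salts if p.has_thermo]
    if len(salts_with_data) == 2:
        a, b = salts_with_data
        try:
            report.x_eu, report.delta_tm, report.f_max = salt_pair_metrics(a, b)
            report.favored_salt = a.name if a.t_fus >= b.t_fus else b.name
        except NoEutecticError as exc:
            report.notes.append(f"salt-pair eutectic not found: {exc}")

    if dominating is not None and any(d.name == dominating for d in double_salts):
        report.verdict = "blocked_by_double_salt"
        report.notes.append(
            "the double salt dominates at the 1:1 test composition: cooling "
            "there yields the addition compound of both salts — no resolution"
        )
        return report

    if len(salts_with_data) < 2:
        report.verdict = "indeterminate"
        missing = [p.name for p in salts if not p.has_thermo]
        if missing:
            report.notes.append(
                f"salt(s) without melting data: {missing}; an amorphous salt "
                "is expected to stay in the mother liquor, but the "
                "quantitative metrics are skipped"
            )
        else:
            report.notes.append(
                "fewer than two diastereomeric salts in the phase table"
            )
        return report

    if report.delta_tm is None:
        report.verdict = "indeterminate"
        return report

    if report.delta_tm >= MELTING_GAP_THRESHOLD:
        report.verdict = "promising"
    else:
        report.verdict = "inefficient"
        report.notes.append(
            f"melting-point gap {report.delta_tm:.1f} K is below the "
            f"{MELTING_GAP_THRESHOLD:.0f} K rule of thumb"
        )

    if report.favored_salt is not None:
        report.mixing_segment = recommended_mixing_segment(
            diagram, report.favored_salt
        )
    return report
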