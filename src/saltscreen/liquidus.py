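"""Ideal liquidus equations for eutectic melt diagrams.

Two classical closed forms describe the liquidus of an ideal (activity = mole
fraction) melt in equilibrium with a pure crystalline solid:

* the Schröder–van Laar branch of a simple component *i*,

      ln x_i = (ΔH_i / R) (1/T_i^f − 1/T),

* the Prigogine–Defay branch of a 1:1 addition compound (a racemic compound,
  or formally a double salt of two diastereomeric salts),

      ln [4 x (1 − x)] = (ΔH_RS / R) (1/T_RS^f − 1/T),

with T the liquidus temperature (kelvin), T^f the melting point and ΔH the
molar enthalpy of fusion of the solid.  Both are used with the ideal-eutectic
assumption only; no activity coefficients, no heat-capacity corrections.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import R
from .phases import CrystallinePhase

__all__ = [
    "svl_fraction_at_T",
    "svl_T_at_fraction",
    "pd_T_at_fraction",
    "pd_fraction_product_at_T",
]


def _require_thermo(phase: CrystallinePhase) -> tuple[float, float]:
    if not phase.has_thermo:
        raise ValueError(
            f"phase {phase.name!r} lacks melting data (t_fus/dh_fus); "
            "liquidus equations need both"
        )
    return float(phase.t_fus), float(phase.dh_fus)


def svl_fraction_at_T(phase: CrystallinePhase, T):
    """Schröder–van Laar liquidus mole fraction of ``phase`` at temperature T.

    Returns exp[(ΔH/R)(1/T^f − 1/T)].  The value exceeds 1 for T above the
    melting point; it is returned as-is (not clamped) — ``x > 1`` is the
    caller's flag that the liquid is stable and this phase cannot be the
    equilibrium solid at T.  Accepts scalar or array T.
    """
    t_fus, dh_fus = _require_thermo(phase)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    x = np.exp(dh_fus / R * (1.0 / t_fus - 1.0 / T))
    return float(x) if x.ndim == 0 else x


def svl_T_at_fraction(phase: CrystallinePhase, x: float) -> float:
    """Invert the Schröder–van Laar branch: liquidus temperature at fraction x.

    Exact algebraic inverse of :func:`svl_fraction_at_T`; x must lie in
    (0, 1].  x = 1 returns the melting point.
    """
    t_fus, dh_fus = _require_thermo(phase)
    if x <= 0:
        raise ValueError(f"phase {phase.name!r}: fraction must be in (0, 1], got {x}")
    denom = 1.0 / t_fus - R * math.log(x) / dh_fus
    if denom <= 0:
        raise ValueError(
            f"phase {phase.name!r}: no physical liquidus temperature at x={x}"
        )
    return 1.0 / denom


def pd_fraction_product_at_T(compound: CrystallinePhase, T):
    """The Prigogine–Defay product 4·x·(1−x) implied at temperature T.

    Evaluates exp[(ΔH_RS/R)(1/T_RS^f − 1/T)]; equals 1 at the compound's
    melting point and is < 1 below it.  Accepts scalar or array T.
    """
    t_fus, dh_fus = _require_thermo(compound)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    p = np.exp(dh_fus / R * (1.0 / t_fus - 1.0 / T))
    return float(p) if p.ndim == 0 else p


def pd_T_at_fraction(compound: CrystallinePhase, x_s: float) -> float:
    """Prigogine–Defay liquidus temperature of a 1:1 compound at fraction x_s.

    x_s is the mole fraction of one end member on the pseudo-binary section
    through the compound; the branch is symmetric about x_s = 0.5, where it
    attains the compound's melting point.
    """
    t_fus, dh_fus = _require_thermo(compound)
    if not 0.0 < x_s < 1.0:
        raise ValueError(
            f"compound {compound.name!r}: fraction must be in (0, 1), got {x_s}"
        )
    denom = 1.0 / t_fus - R * math.log(4.0 * x_s * (1.0 - x_s)) / dh_fus
    if denom <= 0:
        raise ValueError(
            f"compound {compound.name!r}: no physical liquidus temperature at x={x_s}"
        )
    return 1.0 / denom
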