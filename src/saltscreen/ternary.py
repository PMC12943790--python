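"""Ternary melting phase diagrams assembled from eutectic sub-ternaries.

The full triangular diagram of (enantiomer-1, enantiomer-2, resolving agent)
is put together from sub-ternary systems: triplets of crystalline phases
assumed to be in mutual eutectic relation.  Within a sub-triangle an overall
composition is re-expressed in barycentric coordinates of the three phase
stoichiometries — each phase acting as a single pseudo-component — and the
liquidus surface is the upper envelope of the three Schröder–van Laar
branches evaluated at those coordinates.  The phase with the highest branch
temperature is the dominating solid: the first to crystallize on cooling,
and by the melting-point/solubility inverse correlation the least soluble.

Sub-triangles can be supplied explicitly (the usual practice when a system's
phase relations are known from experiment) or derived automatically by a
Delaunay triangulation of the phase stoichiometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from .constants import R, kelvin_to_celsius
from .liquidus import svl_T_at_fraction, svl_fraction_at_T
from .phases import Composition, CrystallinePhase

__all__ = [
    "SubTernary",
    "TernaryDiagram",
    "DomainMap",
    "triangulate",
    "assemble",
    "ternary_eutectic",
]

_BARY_TOL = 1e-9


def _det3(a: Sequence[float], b: Sequence[float], c: Sequence[float]) -> float:
    """Determinant of three barycentric triples as rows.

    Proportional to the signed area of the triangle they span on the simplex.
    Written as an explicit cofactor expansion so that swapping two simplex
    components negates the value exactly in floating point — which makes
    domain maps of enantiomer-swapped systems mirror bit-for-bit.
    """
    return (
        a[0] * (b[1] * c[2] - b[2] * c[1])
        - a[1] * (b[0] * c[2] - b[2] * c[0])
        + a[2] * (b[0] * c[1] - b[1] * c[0])
    )


def barycentric_in_triangle(
    point: Sequence[float],
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
) -> tuple[float, float, float]:
    """Coordinates (y1, y2, y3) of ``point`` w.r.t. a sub-triangle's vertices.

    All inputs are barycentric triples over the base simplex; the output
    satisfies point = y1·p1 + y2·p2 + y3·p3 with y summing to 1.
    """
    denom = _det3(p1, p2, p3)
    if denom == 0.0:
        raise ValueError("degenerate (zero-area) sub-triangle")
    y1 = _det3(point, p2, p3) / denom
    y2 = _det3(p1, point, p3) / denom
    y3 = _det3(p1, p2, point) / denom
    return (y1, y2, y3)


def simplex_to_xy(coords: Sequence[float]) -> tuple[float, float]:
    """2-D embedding of a barycentric triple (equilateral triangle).

    Component 1 maps to (0, 0), component 2 to (1, 0), component 3 (the
    resolving agent, conventionally drawn at the apex) to (1/2, √3/2).
    """
    c1, c2, c3 = coords
    return (c2 + 0.5 * c3, (np.sqrt(3.0) / 2.0) * c3)


@dataclass(frozen=True)
class SubTernary:
    """A triplet of phases assumed to be in mutual eutectic relation."""

    phases: tuple[CrystallinePhase, CrystallinePhase, CrystallinePhase]

    def __post_init__(self) -> None:
        names = [p.name for p in self.phases]
        if len(set(names)) != 3:
            raise ValueError(f"sub-ternary phases must be distinct: {names}")
        if abs(self.signed_area) < 1e-12:
            raise ValueError(f"degenerate (collinear) sub-ternary: {names}")

    @property
    def names(self) -> tuple[str, str, str]:
        return tuple(p.name for p in self.phases)

    @property
    def signed_area(self) -> float:
        a, b, c = (p.coords for p in self.phases)
        return _det3(a, b, c)

    def barycentric(self, composition: Sequence[float]) -> tuple[float, float, float]:
        a, b, c = (p.coords for p in self.phases)
        return barycentric_in_triangle(tuple(composition), a, b, c)

    def contains(self, composition: Sequence[float], tol: float = _BARY_TOL) -> bool:
        return all(y >= -tol for y in self.barycentric(composition))


def triangulate(
    phases: Sequence[CrystallinePhase],
    explicit_triplets: Optional[Iterable[Sequence[str]]] = None,
) -> list[SubTernary]:
    """Partition the phase set into sub-ternary triangles.

    With ``explicit_triplets`` (sequences of phase names) each triplet is
    validated: names must exist, the triangle must be non-degenerate, and no
    other phase may sit strictly inside it.  Without them, a Delaunay
    triangulation of the phase stoichiometries is used.
    """
    if len(phases) < 3:
        raise ValueError("need at least 3 phases to triangulate")
    by_name = {p.name: p for p in phases}
    if len(by_name) != len(phases):
        raise ValueError("phase names must be unique")

    if explicit_triplets is not None:
        out = []
        for triplet in explicit_triplets:
            names = list(triplet)
            unknown = [n for n in names if n not in by_name]
            if unknown:
                raise ValueError(
                    f"sub-ternary references unknown phase(s) {unknown}; "
                    f"known: {sorted(by_name)}"
                )
            sub = SubTernary(tuple(by_name[n] for n in names))
            _reject_interior_points(sub, phases)
            out.append(sub)
        return out

    xy = np.array([simplex_to_xy(p.coords) for p in phases])
    try:
        tri = Delaunay(xy)
    except Exception as exc:  # qhull raises its own error type on flat input
        raise ValueError(f"cannot triangulate phase coordinates: {exc}") from exc
    if len(tri.simplices) == 0:
        raise ValueError("degenerate (collinear) phase coordinates")
    out = []
    for simplex in tri.simplices:
        sub = SubTernary(tuple(phases[i] for i in simplex))
        _reject_interior_points(sub, phases)
        out.append(sub)
    return out


def _reject_interior_points(
    sub: SubTernary, phases: Sequence[CrystallinePhase]
) -> None:
    for p in phases:
        if p.name in sub.names:
            continue
        y = sub.barycentric(p.coords)
        if all(v > 1e-9 for v in y):
            raise ValueError(
                f"phase {p.name!r} lies strictly inside sub-ternary {sub.names}; "
                "refine the triplet list so every phase is a vertex"
            )


def ternary_eutectic(
    sub: SubTernary,
) -> tuple[Composition, float, tuple[float, float, float]]:
    """Ternary eutectic of a sub-ternary triplet.

    Solves Σ_i exp[(ΔH_i/R)(1/T_i^f − 1/T)] = 1 over the three phases — the
    three-solid extension of the pairwise ideal-eutectic condition.  Each
    term is monotone increasing in T, so the root below the lowest melting
    point is unique.  Returns the eutectic composition on the base simplex
    (fractions mapped through the phase stoichiometries), the temperature in
    kelvin, and the raw phase fractions (y1, y2, y3).
    """
    ph = sub.phases
    for p in ph:
        if not p.has_thermo:
            raise ValueError(f"phase {p.name!r} lacks melting data")

    def residual(T: float) -> float:
        return sum(svl_fraction_at_T(p, T) for p in ph) - 1.0

    hi = min(p.t_fus for p in ph) - 1e-6
    lo = 1.0
    if residual(hi) < 0 or residual(lo) > 0:
        raise ValueError(
            f"no ternary eutectic below the melting points of {sub.names}"
        )
    t_star = brentq(residual, lo, hi, xtol=1e-10, rtol=8.9e-16)
    y = np.array([svl_fraction_at_T(p, t_star) for p in ph])
    y = y / y.sum()
    coords = sum(
        yi * np.asarray(p.coords) for yi, p in zip(y, ph)
    )
    coords = coords / coords.sum()
    return Composition(tuple(coords)), t_star, tuple(y)


@dataclass(frozen=True)
class TernaryDiagram:
    """Assembled triangular diagram: phases, sub-ternaries, eutectics."""

    base_components: tuple[str, str, str]
    phases: tuple[CrystallinePhase, ...]
    subternaries: tuple[SubTernary, ...]
    eutectics: dict = field(default_factory=dict, compare=False)

    def phase(self, name: str) -> CrystallinePhase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(f"unknown phase {name!r}; known: {[p.name for p in self.phases]}")

    def liquidus_at(self, composition) -> tuple[float, str]:
        """Liquidus temperature (kelvin) and dominating solid at a composition.

        The composition is located in its sub-triangle(s); in each, it is
        expressed in barycentric coordinates of the phase stoichiometries and
        the Schröder–van Laar temperature of every phase with a positive
        coordinate is evaluated.  The maximum over all covering sub-triangles
        is returned (on shared edges the covering triangles agree), with ties
        broken toward the lexicographically smallest phase name so results
        are deterministic.
        """
        c = tuple(composition)
        candidates: list[tuple[float, str]] = []
        covered = False
        for sub in self.subternaries:
            y = sub.barycentric(c)
            if any(v < -_BARY_TOL for v in y):
                continue
            covered = True
            for yi, p in zip(y, sub.phases):
                if yi <= _BARY_TOL or not p.has_thermo:
                    continue
                candidates.append((svl_T_at_fraction(p, min(yi, 1.0)), p.name))
        if not covered:
            raise ValueError(
                f"composition {c} lies outside every sub-ternary (outside the "
                "convex hull of the crystalline phases)"
            )
        if not candidates:
            raise ValueError(
                f"no phase with melting data has positive coordinate at {c}"
            )
        t_max = max(t for t, _ in candidates)
        winner = min(name for t, name in candidates if t == t_max)
        return t_max, winner

    def covers(self, composition) -> bool:
        """Whether a composition lies inside some sub-ternary."""
        c = tuple(composition)
        return any(sub.contains(c) for sub in self.subternaries)

    def domain_map(self, grid_density: int = 201) -> "DomainMap":
        """Dominating-phase raster on a barycentric lattice.

        ``grid_density`` is the number of divisions per simplex edge; lattice
        points (i, j, k)/n with i+j+k = n are sampled.  Points outside every
        sub-ternary are invalid (no crystalline phase governs them).
        """
        if grid_density < 2:
            raise ValueError("grid_density must be at least 2")
        n = grid_density
        points, labels, temps = [], [], []
        for i in range(n + 1):
            for j in range(n + 1 - i):
                k = n - i - j
                c = (i / n, j / n, k / n)
                try:
                    t, name = self.liquidus_at(c)
                except ValueError:
                    points.append(c)
                    labels.append(None)
                    temps.append(np.nan)
                    continue
                points.append(c)
                labels.append(name)
                temps.append(t)
        return DomainMap(
            grid_density=n,
            points=tuple(points),
            labels=tuple(labels),
            temperatures=tuple(temps),
        )

    def to_json(self, grid_density: Optional[int] = None) -> dict:
        out = {
            "base_components": list(self.base_components),
            "phases": [p.to_record() for p in self.phases],
            "subternaries": [list(s.names) for s in self.subternaries],
            "ternary_eutectics": {
                "/".join(names): {
                    "composition": list(comp.fractions),
                    "T_eu_K": t,
                    "T_eu_C": kelvin_to_celsius(t),
                }
                for names, (comp, t, _) in self.eutectics.items()
            },
        }
        if grid_density is not None:
            dm = self.domain_map(grid_density)
            out["domain_areas"] = dm.areas()
            out["domain_raster"] = dm.run_length_encoded()
        return out


@dataclass(frozen=True)
class DomainMap:
    """Sampled dominating-phase raster over the composition simplex."""

    grid_density: int
    points: tuple
    labels: tuple
    temperatures: tuple

    def areas(self) -> dict[str, float]:
        """Per-phase domain areas as fractions of the sampled (valid) region."""
        valid = [l for l in self.labels if l is not None]
        if not valid:
            return {}
        counts: dict[str, int] = {}
        for l in valid:
            counts[l] = counts.get(l, 0) + 1
        total = len(valid)
        return {name: cnt / total for name, cnt in sorted(counts.items())}

    def label_at(self, i: int, j: int) -> Optional[str]:
        """Label of lattice point (i, j, n−i−j); linear-scan convenience."""
        n = self.grid_density
        target = (i / n, j / n, (n - i - j) / n)
        for p, l in zip(self.points, self.labels):
            if p == target:
                return l
        raise KeyError((i, j))

    def as_dict(self) -> dict[tuple[float, float, float], Optional[str]]:
        return dict(zip(self.points, self.labels))

    def run_length_encoded(self) -> dict:
        """Compact raster export: labels in lattice iteration order as
        (label, run length) pairs; ``None`` marks invalid cells."""
        runs: list[list] = []
        for label in self.labels:
            if runs and runs[-1][0] == label:
                runs[-1][1] += 1
            else:
                runs.append([label, 1])
        return {"grid_density": self.grid_density, "runs": runs}


def assemble(
    phases: Sequence[CrystallinePhase],
    base_components: Sequence[str] = ("enantiomer-1", "enantiomer-2", "resolving-agent"),
    explicit_triplets: Optional[Iterable[Sequence[str]]] = None,
    compute_eutectics: bool = True,
) -> TernaryDiagram:
    """Build the full ternary diagram from a phase table.

    Sub-ternaries come from ``explicit_triplets`` when given, else from a
    Delaunay triangulation.  Per-sub-triangle ternary eutectics are computed
    where all three phases carry melting data.
    """
    subs = triangulate(phases, explicit_triplets)
    eutectics: dict = {}
    if compute_eutectics:
        for sub in subs:
            if all(p.has_thermo for p in sub.phases):
                try:
                    eutectics[sub.names] = ternary_eutectic(sub)
                except ValueError:
                    pass  # recorded as absent: no ternary eutectic in range
    return TernaryDiagram(
        base_components=tuple(base_components),
        phases=tuple(phases),
        subternaries=tuple(subs),
        eutectics=eutectics,
    )
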