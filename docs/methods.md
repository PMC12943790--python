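# Methods

## Scope and assumptions

`saltscreen` models the equilibrium *melt* phase behavior of a ternary
chiral resolution system — two enantiomers plus a resolving agent — from
per-phase DSC data, as a proxy for the solution-phase (eutonic) behavior
that actually governs fractional crystallization. Everything rests on two
assumptions, stated up front because they bound what the outputs mean:

1. **Ideality.** Every liquidus is an ideal-solution branch: activity equals
   mole fraction, no activity coefficients, no NRTL/UNIQUAC, no ΔCp
   corrections. Melting points and enthalpies of fusion are taken exactly as
   ingested (DSC peak temperatures; decomposition-corrected enthalpies are
   inputs, not modeled).
2. **Complete phase inventory with eutectic relations.** All crystalline
   phases of the system are known, each behaves as a single pseudo-component,
   and every adjacent pair/triplet is in simple eutectic relation. Solid
   solutions (pseudo-racemates), peritectics and incongruent melting are out
   of scope; a missing phase (e.g. an undiscovered double salt) silently
   invalidates the verdict, which is precisely why the blocked cases in the
   packaged data are instructive.

## Thermodynamic kernel

Temperatures are kelvin and enthalpies J/mol everywhere inside the package;
°C and J/g exist only at ingest/report boundaries (+273.15; J/g × molar
mass, with molar masses computed from Hill-notation formulas via an embedded
IUPAC-2021 conventional atomic-weight table). The gas constant is fixed at
R = 8.314 J/(mol K) so derived numbers are stable to the last printed digit.

Branches:

- Schröder–van Laar: x(T) = exp[(ΔH/R)(1/T_f − 1/T)], with the exact
  algebraic inverse T(x) = 1/(1/T_f − R ln x / ΔH). x(T) > 1 is returned
  unclamped: it flags that the liquid is stable and the phase cannot be the
  equilibrium solid at that temperature.
- Prigogine–Defay for 1:1 addition compounds:
  T(x) = 1/(1/T_RS − R ln[4x(1−x)]/ΔH_RS), symmetric about x = 0.5 where it
  attains T_RS. A double salt of two diastereomeric salts is handled by the
  same branch on the salt–salt section, with the compound counting as
  0.5 + 0.5 of the end members in the section bookkeeping (the natural
  reading of treating it "formally" as a racemic-compound analogue).

## Eutectic solving

All eutectics are bracketed scalar root solves in temperature (Brent), never
in composition:

- **Pairwise:** x_A(T) + x_B(T) = 1 on T ∈ (1 K, min T_f − 1e−6). Both
  terms are strictly increasing in T, so the root is unique; it is refined
  to machine precision (well inside the 1e−8 fraction-residual contract).
  Identical (T_f, ΔH) pairs are reported as x = 0.5 with a degeneracy flag
  rather than solved (the branches coincide over an interval).
- **Side eutectics of a compound section:** the side phase's
  Schröder–van Laar fraction is substituted into the Prigogine–Defay
  condition and the residual g(T) = ln[4x(1−x)] − (ΔH_RS/R)(1/T_RS − 1/T)
  is scanned downward from just below both melting points (4096-point
  grid); the first sign change is refined by Brent. Taking the highest-T
  crossing selects the physical eutectic (the upper envelope's corner). If
  g never crosses zero the compound branch lies below the side branch
  everywhere and a `CompoundMetastableError` is raised; this occurs when
  ΔH_RS < ΔH_side with a sufficiently low compound melting point. The
  limiting behavior is worth recording: with the compound melting at the
  end members' own temperature, growing ΔH_RS flattens its branch toward
  the constant T_RS, so the side eutectics move monotonically toward the
  pure ends x → 0, 1 (not toward 0.5 — the compound's domain widens, not
  narrows).
- **Ternary:** Σ over the triplet of exp[(ΔH_i/R)(1/T_f,i − 1/T)] = 1, same
  bracketing; the eutectic composition is the fraction triple at the root
  mapped through the phase stoichiometries onto the base simplex.

Independent verification throughout the test suite uses brute-force
0.001 K temperature scans written directly from the closed forms; solver
and scan agree to < 0.001 K (the tests assert 0.01 K).

## Ternary assembly

Coordinates are barycentric mole-fraction-of-molecules triples ordered
(enantiomer-1, enantiomer-2, agent): 1:1 salts at (0.5, 0, 0.5) and
(0, 0.5, 0.5), the racemic compound at (0.5, 0.5, 0), a 2:1 amine:acid
double salt at (0.25, 0.25, 0.5) — which is also the conventional 1:1
racemate:agent test composition, the geometric heart of the double-salt
blocking rule.

Sub-ternaries are taken from an explicit triplet list when the system's
phase relations are known (all packaged cases carry one, mirroring how such
diagrams are joined by hand); otherwise from a Delaunay triangulation of
the phase points in a 2-D equilateral embedding, with any triangle
containing a foreign phase strictly in its interior rejected. Explicit
triplets always override: automatic triangulation cannot know chemistry.

Within a sub-triangle, a composition is re-expressed in barycentric
coordinates of the three phase stoichiometries and the liquidus surface is
the maximum of the three Schröder–van Laar branches at those coordinates.
This three-phase ideal envelope is the standard construction for the
surface *off* the binary sections, where no closed form is printed in the
source data conventions; the binary sections themselves (where
Prigogine–Defay refinement applies) remain the quantitative curves of
record, and the test suite checks that the surface restricted to a
salt–salt edge reproduces the two-branch binary envelope exactly.

Barycentric coordinates are computed by an explicit 3×3 cofactor expansion
rather than a linear solve. This is deliberate: swapping the two enantiomer
components permutes the determinant's products without changing their
values, so enantiomer-relabeled systems produce bit-identical mirrored
domain maps — an exactness the tests assert. Dominating-phase ties (which
occur on symmetry lines) are broken toward the lexicographically smallest
phase name, deterministically.

Domain maps sample the lattice {(i, j, k)/n : i+j+k = n} (default n = 201
divisions per edge); points outside every sub-ternary are invalid (no
crystalline phase governs them — e.g. the agent corner of a system whose
agent never crystallizes). Areas are reported as fractions of the valid
sampled region.

## Verdict rules

Applied in order: (1) if a double-salt phase dominates at the test
composition → `blocked_by_double_salt`; (2) if either diastereomeric salt
lacks melting data → `indeterminate` (an amorphous salt is expected to stay
in the mother liquor, but no quantitative claim is made); (3) melting gap
ΔT_m ≥ 20 K → `promising`, else `inefficient`. x_eu is always reported as
the fraction of the *higher-melting* salt, and F_max = 2 − 1/(1 − x_eu).
The recommended mixing segment is the widest contiguous run of the
racemate–agent mixing line (agent fraction t ∈ [0, 1]) on which the favored
salt dominates, sampled at 401 points.

## Synthetic systems

`generate_synthetic_system` emulates the structure, not the chemistry, of
real screening systems: an enantiomer pair with identical data (physically
exact), a crystalline agent, salts at the edge midpoints, optional racemic
compound and double salt, with canonical sub-ternary triplets attached.
Melting points draw uniformly from [330, 470] K and enthalpies from
[15, 70] kJ/mol — brackets around the packaged cases' values — with the
1:1 addition compounds drawing enthalpy from the upper half of the range,
mirroring the empirical pattern that such compounds melt with roughly twice
the enthalpy of their components. What passing synthetic sweeps demonstrate
is solver correctness and invariant preservation under the model's own
assumptions; they say nothing about non-ideality, missed phases, kinetics
or solvent effects in real systems.

## Problem sizes

The test suite runs 1000-system solver-vs-scan sweeps (0.001 K grids),
100-system identity/ordering sweeps, and 30–80-division domain maps; the
acceptance script uses 200 synthetic systems and the three packaged cases.
These sizes give sub-millikelvin agreement margins at interactive runtimes;
nothing in the method scales worse than linearly in grid points.

## Known limitations

- F_max is a theoretical ceiling, not a yield prediction; kinetic effects,
  solvates and solvent choice are outside the model.
- The melt diagram is a proxy: the eutonic composition is *estimated* by the
  melt eutectic, an approximation that is the method's premise, not its
  conclusion.
- The 20 K rule is a heuristic encoded as a hard threshold on as-ingested
  peak temperatures; no uncertainty propagation is attempted.
- Liquidus surfaces near compound phases are not Prigogine–Defay-refined in
  2-D (only on binary sections); domain boundaries drawn near a racemic
  compound or double salt are correspondingly approximate.
- Fractions > 1 returned by the Schröder–van Laar branch are the caller's
  responsibility to interpret (liquid stable); they are never silently
  clamped.
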