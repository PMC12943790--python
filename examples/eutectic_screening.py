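"""Screen a diastereomeric salt pair from raw DSC numbers.

Builds the two 1:1 pregabalin–2-chloromandelate salts straight from their
measured melting points (°C) and specific enthalpies of fusion (J/g, molar
mass derived from the salt formula), solves their binary eutectic, and turns
it into the resolvability metrics.
"""

from saltscreen import CrystallinePhase, fogassy_parameter, solve_simple_eutectic

high = CrystallinePhase.from_record({
    "name": "S-S salt", "role": "diastereomeric_salt",
    "coords": (0.5, 0.0, 0.5), "formula": "C16H24ClNO5",
    "t_fus": 150, "t_fus_unit": "C", "dh_fus": 171, "dh_fus_unit": "J/g",
})
low = CrystallinePhase.from_record({
    "name": "S-R salt", "role": "diastereomeric_salt",
    "coords": (0.0, 0.5, 0.5), "formula": "C16H24ClNO5",
    "t_fus": 100, "t_fus_unit": "C", "dh_fus": 75, "dh_fus_unit": "J/g",
})

eu = solve_simple_eutectic(high, low)
print(f"salt molar mass          : {high.molar_mass:.2f} g/mol")
print(f"molar enthalpies         : {high.dh_fus:.0f} / {low.dh_fus:.0f} J/mol")
print(f"eutectic temperature     : {eu.T_eu_celsius:.1f} C ({eu.T_eu:.1f} K)")
print(f"x_eu (higher-melting salt): {eu.x_A:.3f}")
print(f"Fogassy parameter F_max  : {fogassy_parameter(eu.x_A):.3f}")
print()
print("x_eu is the favored salt's share of the lowest-melting (and, by the")
print("eutonic analogy, most soluble) salt mixture: the smaller it is, the")
print("purer the first crystals, and F_max = 2 - 1/(1 - x_eu) caps the")
print("theoretical resolution efficiency.")
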