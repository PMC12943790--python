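"""Double-salt blocking: why some salt pairs cannot resolve anything.

Both chloromandelic-acid/1-cyclohexylethylamine systems form, beyond the
expected diastereomeric salt pair, a 2:1 amine:acid double salt that sits
exactly at the 1:1 racemate:agent test composition — and dominates there.
Cooling the standard test mixture crystallizes the double salt, which
contains both enantiomers in equal amounts: no resolution.
"""

from saltscreen import load_case, resolution_verdict

for label in ("case1_4ClMA_CHEA", "case2_2ClMA_CHEA"):
    case = load_case(label)
    report = resolution_verdict(case.diagram(compute_eutectics=False))
    print(f"== {label} ==")
    print(report.summary())
    print()

print("Both verdicts are blocked_by_double_salt even though the salt-pair")
print("melting gaps alone would not have looked hopeless: the phase that")
print("actually crystallizes at the 1:1 mixing point decides the outcome.")
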