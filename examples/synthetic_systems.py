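"""Seeded synthetic systems: property checks at scale.

Generates random ideal-eutectic resolution systems with the canonical
topology (enantiomer pair, resolving agent, salt pair, optional compounds),
runs the screening end to end, and cross-checks the eutectic solver against
a brute-force 0.001 K temperature scan.
"""

import numpy as np

from saltscreen import generate_synthetic_system, resolution_verdict, solve_simple_eutectic
from saltscreen.constants import R

verdicts: dict[str, int] = {}
worst = 0.0
for seed in range(50):
    study = generate_synthetic_system(seed, with_double_salt=(seed % 5 == 0))
    report = resolution_verdict(study.diagram(compute_eutectics=False))
    verdicts[report.verdict] = verdicts.get(report.verdict, 0) + 1

    s1, s2 = study.phase("S1"), study.phase("S2")
    eu = solve_simple_eutectic(s1, s2)
    T = np.arange(1.0, min(s1.t_fus, s2.t_fus) - 1e-6, 0.001)
    resid = sum(
        np.exp(p.dh_fus / R * (1 / p.t_fus - 1 / T)) for p in (s1, s2)
    ) - 1.0
    t_scan = T[np.argmin(np.abs(resid))]
    worst = max(worst, abs(eu.T_eu - t_scan))

print("verdict tally over 50 seeded systems:", verdicts)
print(f"largest solver-vs-scan eutectic temperature gap: {worst:.2e} K")
print()
print("Every system with a double salt is blocked (the double salt owns the")
print("1:1 test point by construction); the rest split on the 20 K")
print("melting-gap rule. The solver agrees with the brute-force scan to")
print("well under the 0.001 K grid spacing.")
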