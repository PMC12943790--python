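# saltscreen

Predicting the success of chiral resolutions by diastereomeric-salt
fractional crystallization, from nothing more than DSC melting data.

## The problem

Resolving a racemate with a chiral agent works by crystallizing the two
diastereomeric salts the agent forms with the two enantiomers: the salts
differ in melting point and solubility, so one precipitates preferentially.
Whether this actually works — and how well it can possibly work — is
governed by the equilibrium phase behavior of the ternary system
(enantiomer-1, enantiomer-2, resolving agent). Measuring solubility
(eutonic) diagrams is tedious; but under the ideal-eutectic assumption the
*melt* phase diagram, built from a handful of DSC melting points and
enthalpies of fusion, estimates it. `saltscreen` automates that construction
for laboratory chemists screening resolving agents.

## The model

Each crystalline phase *i* (enantiomer, racemic compound, diastereomeric
salt, double salt, the agent itself) enters with its melting point
*T*<sup>f</sup><sub>i</sub> (K) and molar enthalpy of fusion
*ΔH*<sub>i</sub> (J/mol). Ideal liquidus branches:

- Schröder–van Laar (simple solid):
  ln *x*<sub>i</sub> = (*ΔH*<sub>i</sub>/*R*) (1/*T*<sup>f</sup><sub>i</sub> − 1/*T*)
- Prigogine–Defay (1:1 addition compound — a racemic compound, or formally a
  double salt of the salt pair):
  ln [4*x*(1 − *x*)] = (*ΔH*<sub>RS</sub>/*R*) (1/*T*<sup>f</sup><sub>RS</sub> − 1/*T*)

Binary eutectics solve Σ*x*<sub>i</sub>(*T*) = 1 pairwise; ternary eutectics
solve the same condition over a phase triplet. The triangular diagram is
assembled from sub-ternaries (triplets of phases in assumed eutectic
relation), and the dominating solid at any composition is the phase with
the highest liquidus temperature there.

Screening metrics derived from the diagram:

- **x_eu** — the eutectic fraction of the higher-melting (favored,
  less-soluble) salt, estimating the eutonic ratio;
- **F_max = 2 − 1/(1 − x_eu)** — the Fogassy resolubility parameter, the
  theoretical maximum resolution efficiency;
- **the 20 K rule** — an efficient resolution needs at least a 20 K gap
  between the salt pair's melting points;
- **double-salt blocking** — if an addition compound of the two salts
  dominates at the 1:1 racemate:agent test composition (0.25, 0.25, 0.5),
  no initial mixing ratio favors either salt and resolution fails.

## Worked example

Three case studies ship with the package. The promising one — racemic
2-chloromandelic acid resolved with (S)-pregabalin, salts melting at 150 °C
(171 J/g) and 100 °C (75 J/g):

```python
from saltscreen import load_case, resolution_verdict

case = load_case("case3_2ClMA_pregabalin")
print(resolution_verdict(case.diagram()).summary())
```

```
verdict: promising
diastereomeric salt pair: 4'', 5''
melting-point gap: 50.0 K
eutectic fraction of favored salt (4''): x_eu = 0.086
Fogassy parameter F_max = 0.906
dominating solid at the 1:1 test composition: 4''
recommended racemate:agent mixing line segment (agent fraction 0.052–0.557)
note: dominating solid at 1:1 test point: 4'' (liquidus 133.2 °C)
```

The 50 K melting gap makes the high-melting salt 4'' dominate 49 % of the
composition triangle, including the 1:1 test point; only 8.6 mol% of it is
lost to the eutectic, capping the theoretical efficiency at F_max = 0.906.
By contrast, both chloromandelic-acid/1-cyclohexylethylamine cases return
`blocked_by_double_salt`: their 2:1 amine:acid double salts sit exactly at
— and dominate — the test composition (see
`examples/double_salt_blocking.py`).

The `examples/` directory has one short script per capability (salt-pair
screening from raw DSC numbers, ternary assembly and plotting, double-salt
blocking, synthetic-system sweeps). A thin CLI mirrors the library:

```sh
saltscreen eutectic --case case3_2ClMA_pregabalin "4''" "5''"
saltscreen diagram --case case1_4ClMA_CHEA --out out/
saltscreen synth --seed 7 --double-salt --out synthetic.json
```

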