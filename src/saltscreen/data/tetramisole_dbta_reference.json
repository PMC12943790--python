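{
  "label": "tetramisole_dbta_reference",
  "description": "Topology-only reference: resolution of racemic tetramisole base with O,O'-dibenzoyl-(R,R)-tartaric acid (DBTA). A 1:1 double salt (salt 3) again occupies the 1:1 test composition, but resolution succeeds through an additional salt of different stoichiometry: the 2:1 base:acid salt (salt 1) on the (S)-TET-DBTA edge, reached by using less than half an equivalent of the diacid. No melting data are carried (none published); the fixture exercises triangulation and verdict logic on an 8-phase topology.",
  "base_components": ["(S)-TET", "(R)-TET", "(R,R)-DBTA"],
  "explicit_triplets": [
    ["S-TET", "rac-TET", "salt1"],
    ["rac-TET", "salt1", "salt2"],
    ["rac-TET", "salt2", "salt3"],
    ["rac-TET", "salt3", "salt4"],
    ["rac-TET", "R-TET", "salt4"],
    ["salt2", "salt3", "DBTA"],
    ["salt3", "salt4", "DBTA"]
  ],
  "phases": [
    {"name": "S-TET", "role": "enantiomer", "coords": [1.0, 0.0, 0.0],
     "provenance": {"coords": "pure (S)-tetramisole corner"}},
    {"name": "R-TET", "role": "enantiomer", "coords": [0.0, 1.0, 0.0],
     "provenance": {"coords": "pure (R)-tetramisole corner"}},
    {"name": "rac-TET", "role": "racemic_compound", "coords": [0.5, 0.5, 0.0],
     "provenance": {"coords": "racemic tetramisole, 1:1 stoichiometry"}},
    {"name": "DBTA", "role": "resolving_agent", "coords": [0.0, 0.0, 1.0],
     "provenance": {"coords": "pure resolving agent corner"}},
    {"name": "salt1", "role": "other_salt", "coords": [0.6666666666666666, 0.0, 0.3333333333333333],
     "provenance": {"coords": "2:1 (S)-TET:DBTA salt, the key phase of the successful resolution"}},
    {"name": "salt2", "role": "diastereomeric_salt", "coords": [0.5, 0.0, 0.5],
     "provenance": {"coords": "1:1 (S)-TET:DBTA diastereomeric salt"}},
    {"name": "salt3", "role": "double_salt", "coords": [0.25, 0.25, 0.5],
     "provenance": {"coords": "double salt of the diastereomeric pair, at the 1:1 test composition"}},
    {"name": "salt4", "role": "diastereomeric_salt", "coords": [0.0, 0.5, 0.5],
     "provenance": {"coords": "1:1 (R)-TET:DBTA diastereomeric salt"}}
  ],
  "extras": {}
}
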