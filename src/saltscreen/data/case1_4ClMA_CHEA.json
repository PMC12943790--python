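{
  "label": "case1_4ClMA_CHEA",
  "description": "Resolution screening system of racemic 4-chloromandelic acid with (S)-1-cyclohexylethylamine. Three 1:1 ammonium carboxylate salts exist: the diastereomeric pair (4, 6) and their 2:1 amine:acid double salt (5), which sits at the 1:1 racemate:agent test composition.",
  "base_components": ["(S)-4ClMA", "(R)-4ClMA", "(S)-CHEA"],
  "explicit_triplets": [
    ["1", "2", "4"],
    ["2", "4", "5"],
    ["2", "5", "6"],
    ["2", "3", "6"]
  ],
  "phases": [
    {
      "name": "1",
      "role": "enantiomer",
      "coords": [1.0, 0.0, 0.0],
      "t_fus": 396.3,
      "t_fus_unit": "K",
      "dh_fus": 21850,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of (S)-4-chloromandelic acid, published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    },
    {
      "name": "2",
      "role": "racemic_compound",
      "coords": [0.5, 0.5, 0.0],
      "t_fus": 395.4,
      "t_fus_unit": "K",
      "dh_fus": 50418,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of rac-4-chloromandelic acid (racemic compound), published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    },
    {
      "name": "3",
      "role": "enantiomer",
      "coords": [0.0, 1.0, 0.0],
      "t_fus": 396.3,
      "t_fus_unit": "K",
      "dh_fus": 21850,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "assumed identical to the (S)-enantiomer (mirror image)",
        "dh_fus": "assumed identical to the (S)-enantiomer (mirror image)"
      }
    },
    {
      "name": "4",
      "role": "diastereomeric_salt",
      "coords": [0.5, 0.0, 0.5],
      "t_fus": 434.1,
      "t_fus_unit": "K",
      "dh_fus": 31585,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of the (S)-CHEA-(S)-4ClMA salt, published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    },
    {
      "name": "5",
      "role": "double_salt",
      "coords": [0.25, 0.25, 0.5],
      "t_fus": 415.1,
      "t_fus_unit": "K",
      "dh_fus": 65680,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of the [(S)-CHEA]2-(R&S)-4ClMA double salt, published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    },
    {
      "name": "6",
      "role": "diastereomeric_salt",
      "coords": [0.0, 0.5, 0.5],
      "t_fus": 430.1,
      "t_fus_unit": "K",
      "dh_fus": 26736,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of the (S)-CHEA-(R)-4ClMA salt, published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    }
  ],
  "extras": {}
}
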