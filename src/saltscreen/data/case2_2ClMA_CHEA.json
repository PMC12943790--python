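{
  "label": "case2_2ClMA_CHEA",
  "description": "Resolution screening system of racemic 2-chloromandelic acid with (S)-1-cyclohexylethylamine. As in the 4-chloro system, a 2:1 amine:acid double salt (5') exists beyond the diastereomeric pair (4', 6') and sits at the 1:1 racemate:agent test composition.",
  "base_components": ["(S)-2ClMA", "(R)-2ClMA", "(S)-CHEA"],
  "explicit_triplets": [
    ["1'", "2'", "4'"],
    ["2'", "4'", "5'"],
    ["2'", "5'", "6'"],
    ["2'", "3'", "6'"]
  ],
  "phases": [
    {
      "name": "1'",
      "role": "enantiomer",
      "coords": [1.0, 0.0, 0.0],
      "t_fus": 393.1,
      "t_fus_unit": "K",
      "dh_fus": 24033,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of (S)-2-chloromandelic acid, published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    },
    {
      "name": "2'",
      "role": "racemic_compound",
      "coords": [0.5, 0.5, 0.0],
      "t_fus": 362.1,
      "t_fus_unit": "K",
      "dh_fus": 43076,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of rac-2-chloromandelic acid (racemic compound), published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    },
    {
      "name": "3'",
      "role": "enantiomer",
      "coords": [0.0, 1.0, 0.0],
      "t_fus": 393.1,
      "t_fus_unit": "K",
      "dh_fus": 24033,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "assumed identical to the (S)-enantiomer (mirror image)",
        "dh_fus": "assumed identical to the (S)-enantiomer (mirror image)"
      }
    },
    {
      "name": "4'",
      "role": "diastereomeric_salt",
      "coords": [0.5, 0.0, 0.5],
      "t_fus": 413.1,
      "t_fus_unit": "K",
      "dh_fus": 13200,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of the (S)-CHEA-(S)-2ClMA salt, published value",
        "dh_fus": "published DSC enthalpy of fusion; carried as printed (notably smaller than the 4-chloro salts)"
      }
    },
    {
      "name": "5'",
      "role": "double_salt",
      "coords": [0.25, 0.25, 0.5],
      "t_fus": 424.6,
      "t_fus_unit": "K",
      "dh_fus": 54832,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of the [(S)-CHEA]2-(R&S)-2ClMA double salt, published value",
        "dh_fus": "published DSC enthalpy of fusion"
      }
    },
    {
      "name": "6'",
      "role": "diastereomeric_salt",
      "coords": [0.0, 0.5, 0.5],
      "t_fus": 400.6,
      "t_fus_unit": "K",
      "dh_fus": 13714,
      "dh_fus_unit": "J/mol",
      "provenance": {
        "t_fus": "DSC peak temperature of the (S)-CHEA-(R)-2ClMA salt, published value",
        "dh_fus": "published DSC enthalpy of fusion; carried as printed (notably smaller than the 4-chloro salts)"
      }
    }
  ],
  "extras": {}
}
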