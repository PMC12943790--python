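{
  "label": "case3_2ClMA_pregabalin",
  "description": "Resolution screening system of racemic 2-chloromandelic acid with (S)-pregabalin [(S)-3-isobutyl-gamma-aminobutyric acid]. No double salt exists; the diastereomeric 1:1 salts 4'' (S-S, mp 150 C) and 5'' (S-R, mp 100 C) differ by 50 K in melting point, giving a very asymmetric diagram and a promising resolution. Salt enthalpies were measured as specific values (J/g) and are converted to molar through the salt formula C16H24ClNO5; the pregabalin enthalpy (312 J/g, corrected for the decomposition escorting its fusion) is converted through C8H17NO2. The pairing of 75/171/312 J/g with the 100/150/199 C melting events follows their parallel order of listing.",
  "base_components": ["(S)-2ClMA", "(R)-2ClMA", "(S)-pregabalin"],
  "explicit_triplets": [
    ["1''", "2''", "4''"],
    ["2''", "4''", "5''"],
    ["2''", "3''", "5''"],
    ["4''", "5''", "6''"]
  ],
  "phases": [
    {
      "name": "1''",
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
      "name": "2''",
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
      "name": "3''",
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
      "name": "4''",
      "role": "diastereomeric_salt",
      "formula": "C16H24ClNO5",
      "coords": [0.5, 0.0, 0.5],
      "t_fus": 150,
      "t_fus_unit": "C",
      "dh_fus": 171,
      "dh_fus_unit": "J/g",
      "provenance": {
        "t_fus": "measured DSC melting point of the (S)-pregabalin-(S)-2ClMA salt",
        "dh_fus": "derived: measured 171 J/g x molar mass of C16H24ClNO5"
      }
    },
    {
      "name": "5''",
      "role": "diastereomeric_salt",
      "formula": "C16H24ClNO5",
      "coords": [0.0, 0.5, 0.5],
      "t_fus": 100,
      "t_fus_unit": "C",
      "dh_fus": 75,
      "dh_fus_unit": "J/g",
      "provenance": {
        "t_fus": "measured DSC melting point of the (S)-pregabalin-(R)-2ClMA salt",
        "dh_fus": "derived: measured 75 J/g x molar mass of C16H24ClNO5"
      }
    },
    {
      "name": "6''",
      "role": "resolving_agent",
      "formula": "C8H17NO2",
      "coords": [0.0, 0.0, 1.0],
      "t_fus": 199,
      "t_fus_unit": "C",
      "dh_fus": 312,
      "dh_fus_unit": "J/g",
      "provenance": {
        "t_fus": "measured DSC melting point of (S)-pregabalin",
        "dh_fus": "derived: 312 J/g (corrected for decomposition escorting fusion) x molar mass of C8H17NO2"
      }
    }
  ],
  "extras": {}
}
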