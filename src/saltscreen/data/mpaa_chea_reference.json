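{
  "label": "mpaa_chea_reference",
  "description": "Literature reference point: resolution of racemic 2-methoxy-2-phenylacetic acid (MPAA) with (R)-1-cyclohexylethylamine. Only the published summary numbers are carried (no thermodynamic phase table was printed for this system): the salt-pair eutectic composition x_eu = 0.30 of the favored salt and a ca. 25 K melting-point gap, giving Fogassy parameter F_max = 0.57. Exercises the resolvability metrics only.",
  "base_components": ["(S)-MPAA", "(R)-MPAA", "(R)-CHEA"],
  "explicit_triplets": [],
  "phases": [],
  "extras": {
    "x_eu": 0.30,
    "delta_tm_K": 25.0,
    "f_max_quoted": 0.57
  }
}
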