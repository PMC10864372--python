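{
  "g": 2.00232,
  "B0_mT": 0.15,
  "Bexp_mT": 100.0,
  "isotope_table": [
    {"weight": 0.9, "spin": 0.0, "a_mT": 0.0, "note": "24Mg + 26Mg lumped (both spin-0)"},
    {"weight": 0.1, "spin": 2.5, "a_mT": -11.22, "note": "25Mg, natural abundance 10%"}
  ],
  "pathways": {
    "ser": {"a_A_mT": 7.45, "spin_A": 0.5, "label": "Ser",
            "note": "serine oxyradical; dominant hyperfine from one H nucleus"},
    "tyr": {"a_A_mT": 1.86, "spin_A": 0.5, "label": "Tyr",
            "note": "tyrosine oxyradical; dominant hyperfine from one H nucleus"}
  },
  "reference_kinetics": {"k_per_s": 2e6, "r_per_s": 1e6}
}
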