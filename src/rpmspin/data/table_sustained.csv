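# Ca2+ uptake into immature rat hippocampal cells, sustained exposure:
# cultured 3 days in vitro under a 100 mT static field vs control.
# Percentages are relative to the maximal reading after 10 uM Ca2+
# ionophore (A23187); values are approximate, extracted from published
# plots.  printed_ratio is the 1-d.p. field/control ratio as published.
nmda_um,control_pct,field_pct,printed_ratio
1,6.2,11.5,1.8
3,15.1,23.7,1.6
10,21.1,30.6,1.4
30,24.7,33.2,1.3
100,26.9,33.7,1.2
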