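# Ca2+ uptake into immature rat hippocampal cells, repeated exposure:
# 100 mT static field 15 min/day for 8 days vs control.
# Percentages are relative to the maximal reading after 10 uM Ca2+
# ionophore (A23187); values are approximate, extracted from published
# plots.  printed_ratio is the 1-d.p. field/control ratio as published.
nmda_um,control_pct,field_pct,printed_ratio
1,3.9,6.2,1.6
3,10.2,16.3,1.6
10,17.9,25.8,1.4
30,22.8,28.2,1.2
100,25.1,28.4,1.1
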