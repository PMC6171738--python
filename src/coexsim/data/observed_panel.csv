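transmitter,count_mean,count_sd,provenance
TK,12.16,0.55,immunocytochemistry cell counts per antennal lobe (n=6 brains)
FMRF,58.16,17.48,immunocytochemistry cell counts per antennal lobe (n=6 brains)
Mas-AT,143.58,24.38,immunocytochemistry cell counts per antennal lobe (n=6 brains)
MIP,150.66,16.79,immunocytochemistry cell counts per antennal lobe (n=6 brains)
AST-A,47.4,12.83,immunocytochemistry cell counts per antennal lobe (n=6 brains)
GABA,170,0,reported GABAergic LN total; SD not reported
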