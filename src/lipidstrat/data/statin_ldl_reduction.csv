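atorvastatin_dose_mg,ldl_reduction_fraction
0,0.00
5,0.31
10,0.37
20,0.43
40,0.49
80,0.55
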