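name	coverage	coverage_sd	printed_unit
PSAG28	2.55	0.23	ng/mm2
PSAG24	0.89	0.2	ng/cm2
ΔPSap4#5	0.77	0.19	ng/cm2
PSAG212	0.65	0.18	ng/cm2
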