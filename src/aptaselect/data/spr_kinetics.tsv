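name	ka_1e3_per_M_s	ka_sd	kd_1e-3_per_s	kd_sd	KA_1e6_per_M	KA_sd
PSAG24	3.37	0.62	12.34	0.58	0.27	0.04
PSAG28	6.62	0.77	6.7	0.37	0.99	0.06
PSAG212	3.11	0.5	11.23	0.8	0.28	0.03
ΔPSap4#5	4.2	0.62	7.08	0.23	0.59	0.07
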