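name	delta_f_mean	delta_f_sd	rank_experiment
PSAG24	131.3	4.9	2
PSAG28	166.2	6.7	1
PSAG212	59.5	5.8	4
ΔPSap4#5	76.1	2.1	3
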