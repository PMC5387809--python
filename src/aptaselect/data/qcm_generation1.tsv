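name	delta_f_mean	delta_f_sd	rank_experiment	rank_simulation
PSAG11	19.2	1.7	8	1
PSAG15	108.2	14	1	7
PSAG17	37.3	1.9	6	8
PSAG112	71.7	1.3	4	5
PSAG114	63	5.4	5	2
PSAG117	82.9	5.8	3	6
PSAG118	24.9	3.9	7	4
PSAG119	91.3	9.7	2	3
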