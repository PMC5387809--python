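name	sequence	mfe	dotbracket	zdock	zrank	rank
PSAG11	TTTTTCTGTTGCCCGGAACGTCGTGGCCCTTT	-5.6	..........((((((....))).))).....	17.34	-81.44	1
PSAG12	TTTTTGTGGTGTTTATTGTTTACTGTCCCTTT	-0.2	.......((((.........))))........	49.27	-60.91
PSAG13	TTTTTCTGGTGTTTATTCCATCAAATATCTTT	-3.1	.......(((((((........)))))))...	40.03	-60.33
PSAG14	TTTTTAATATCAACTTGGTTTACTGTCCCTTT	-0.2	................((........))....	43.93	-70.08
PSAG15	TTTTTCTGGAATGATTTCCCGGTTGTCTCTTT	-3.3	....((.((((....)))).))..........	38.78	-72.4	7
PSAG16	TTTTTACTTTGTTTATTGTTTACTGTCCCTTT	0	................................	N.A.	N.A.
PSAG17	TTTTTCTGGTCCGGGTACGTTTTTTGGCCTTT	-4.8	.......((.(((((.......)))))))...	39.73	-71.49	8
PSAG18	TTTTTCCGCAGTTTATTGTTTACTGTCCCTTT	-3.5	.......(((((.........)))))......	40.05	-67.55
PSAG19	TTTTTGTGTTGCCCGGAACGTCGTATATCTTT	-0.8	....((((((......)))).)).........	48.16	-68.89
PSAG110	TTTTTAATATCAACTTGCCATCAAGGCCCTTT	-3.3	................(((.....))).....	45.01	-68.88
PSAG111	TTTTTGTGTTGCCATTTCCCGGTTGTCTCTTT	-1.3	..........(((.......))).........	48.6	-64.73
PSAG112	TTTTTACTTAATGCGGAACGTCGTGGCCCTTT	-1.4	............((((....))))........	42.58	-76.89	5
PSAG113	TTTTTGTGTTGCCCGGAACTTTTTTGGCCTTT	-3	..........(((.(((....))).)))....	39.77	-67.01
PSAG114	TTTTTCCGCACCGGGTACGGTCGTGGCCCTTT	-10.8	.....((((((((....)))).))))......	43.45	-78.91	2
PSAG115	TTTTTAATATCAACTTGCCAGGTTGTCTCTTT	-2.7	..........((((((...)))))).......	44.36	-61.84
PSAG116	TTTTTACTTAATGATTTCCCTCAAATATCTTT	0	................................	N.A.	N.A.
PSAG117	TTTTTAATATCCGGGTACGTTTTTTGGCCTTT	-2.4	............((((.((.....))))))..	47.52	-74.57	6
PSAG118	TTTTTCCGCACAACTTGCCATCAAATATCTTT	-1.1	.......(((.....)))..............	46.13	-76.9	4
PSAG119	TTTTTACGCACCGGGTACGTTTTTTGGCCTTT	-2.4	............((((.((.....))))))..	40.41	-77.84	3
PSAG120	TTTTTCCTTAATGATTTCCCGGTTGTCTCTTT	0	................................	N.A.	N.A.
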