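name	sequence	mfe	dotbracket	zdock	zrank	rank
PSAG21	TTTTTCTGGAATGATTAACGTCGTGGCCCTTT	-3.3	.......((.(((((....)))))..))....	43.44	-68.68
PSAG22	TTTTTACTTAATGCGGTCCCGGGGGGCTCTTT	-4.9	..............(((((....)))))....	45.77	-69.16
PSAG23	TTTTTCTGGAATGATTACGTTTTTTGGCCTTT	-1	.......((((((....)))))).........	41.61	-56.12
PSAG24	TTTTTAATATCCGGGTTCCCGGTTGTCTCTTT	-6.7	......(((.((((....)))).)))......	17.54	-70.91	3
PSAG25	TTTTTCTGGAATGATTTCCCGGTTTGGCCTTT	-4.3	.......((((....)))).(((...)))...	45.69	-55.04
PSAG26	TTTTTACGCACCGGGTACGTTTTTGTCTCTTT	-2.6	............(((.(((....))))))...	44.63	-60.12
PSAG27	TTTTTACTTAATGCGTACGTTTTTTGGCCTTT	0	................................	N.A.	N.A.
PSAG28	TTTTTAATATCCGGGGAACGTCGTGGCCCTTT	-4.1	............(((..((...))..)))…	42.64	-86	1
PSAG29	TTTTTACTTAATGCGGACGTTTTTTGGCCTTT	-1.7	............((.((......)).))....	44.51	-65.83
PSAG210	TTTTTACGCACCGGGTAACGTCGTGGCCCTTT	-5.4	............((((.((...)).))))...	42.61	-68.5
PSAG211	TTTTTACTTAATGAATACGTTTTTTGGCCTTT	0	................................	N.A.	N.A.
PSAG212	TTTTTACGCACCGGGTACGTTTTTTGGCCTTT	-2.4	............((((.((.....))))))..	40.41	-77.84	2
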