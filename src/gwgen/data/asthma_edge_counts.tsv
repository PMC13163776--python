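edge_class	candidate	quiet	exacerbation	follow_up
T-G	62864	56734	56539	56531
T-T	25395	19400	20048	20472
T-R	13992	12446	12642	12634
T-L	101	84	82	85
T-M	88	83	82	83
L-G	25	20	17	17
L-T	48	20	36	40
M-G	7022	4345	4296	4403
M-T	1802	1181	1198	1193
M-R	1451	975	947	961
M-L	11	5	5	5
PPI	2785732	707264	707324	640352
Total edges	2898531	802557	803216	736776
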