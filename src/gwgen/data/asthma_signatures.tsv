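stage	target	expression
quiet	CYFIP2	+
quiet	HLA-G	+
quiet	IRF1	-
quiet	IRF5	-
quiet	RHOB	+
exacerbation	IL4	+
exacerbation	KLF4	+
exacerbation	HOXA5	+
exacerbation	ZEB1	+
exacerbation	IL10	-
follow_up	STAT1	+
follow_up	NFKB2	+
follow_up	MUC2	+
follow_up	SPDEF	+
follow_up	SOCS3	-
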