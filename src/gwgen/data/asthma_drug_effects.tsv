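stage	drug	target	effect
quiet	erythromycin	CYFIP2	-
quiet	erythromycin	HLA-G	-
quiet	erythromycin	IRF1	-
quiet	erythromycin	IRF5	0
quiet	erythromycin	RHOB	-
quiet	ergocalciferol	CYFIP2	0
quiet	ergocalciferol	HLA-G	-
quiet	ergocalciferol	IRF1	-
quiet	ergocalciferol	IRF5	+
quiet	ergocalciferol	RHOB	-
quiet	dexamethasone	CYFIP2	+
quiet	dexamethasone	HLA-G	-
quiet	dexamethasone	IRF1	+
quiet	dexamethasone	IRF5	+
quiet	dexamethasone	RHOB	+
quiet	perhexiline	CYFIP2	-
quiet	perhexiline	HLA-G	-
quiet	perhexiline	IRF1	+
quiet	perhexiline	IRF5	0
quiet	perhexiline	RHOB	+
quiet	MK-886	CYFIP2	-
quiet	MK-886	HLA-G	+
quiet	MK-886	IRF1	+
quiet	MK-886	IRF5	+
quiet	MK-886	RHOB	+
exacerbation	Trolox C	IL4	-
exacerbation	Trolox C	KLF4	-
exacerbation	Trolox C	HOXA5	+
exacerbation	Trolox C	ZEB1	-
exacerbation	Trolox C	IL10	+
exacerbation	budesonide	IL4	-
exacerbation	budesonide	KLF4	-
exacerbation	budesonide	HOXA5	+
exacerbation	budesonide	ZEB1	+
exacerbation	budesonide	IL10	+
exacerbation	tomatidine	IL4	-
exacerbation	tomatidine	KLF4	-
exacerbation	tomatidine	HOXA5	-
exacerbation	tomatidine	ZEB1	-
exacerbation	tomatidine	IL10	-
exacerbation	hesperetin	IL4	-
exacerbation	hesperetin	KLF4	-
exacerbation	hesperetin	HOXA5	-
exacerbation	hesperetin	ZEB1	-
exacerbation	hesperetin	IL10	-
exacerbation	trichostatin A	IL4	+
exacerbation	trichostatin A	KLF4	-
exacerbation	trichostatin A	HOXA5	-
exacerbation	trichostatin A	ZEB1	+
exacerbation	trichostatin A	IL10	+
follow_up	chloroquine	STAT1	+
follow_up	chloroquine	NFKB2	-
follow_up	chloroquine	MUC2	-
follow_up	chloroquine	SPDEF	-
follow_up	chloroquine	SOCS3	-
follow_up	imatinib	STAT1	-
follow_up	imatinib	NFKB2	-
follow_up	imatinib	MUC2	+
follow_up	imatinib	SPDEF	+
follow_up	imatinib	SOCS3	+
follow_up	carbamazepine	STAT1	-
follow_up	carbamazepine	NFKB2	-
follow_up	carbamazepine	MUC2	-
follow_up	carbamazepine	SPDEF	-
follow_up	carbamazepine	SOCS3	-
follow_up	iloprost	STAT1	-
follow_up	iloprost	NFKB2	-
follow_up	iloprost	MUC2	+
follow_up	iloprost	SPDEF	-
follow_up	iloprost	SOCS3	+
follow_up	luteolin	STAT1	+
follow_up	luteolin	NFKB2	+
follow_up	luteolin	MUC2	-
follow_up	luteolin	SPDEF	-
follow_up	luteolin	SOCS3	+
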