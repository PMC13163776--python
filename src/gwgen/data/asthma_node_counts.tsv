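node_class	candidate	quiet	exacerbation	follow_up
TFs	1882	1664	1697	1698
lncRNAs	56	54	52	53
miRNAs	104	61	60	61
Receptors	1900	1751	1752	1750
Proteins	10082	9901	9904	9906
Total nodes	14024	13431	13465	13468
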