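species	U	TM	ZnF	BTB	ACBP	GPCR	PK	BPA	IQ	RF	TPR	O	ank_members	proteome_size	printed_percent
A. thaliana	18	40	6	7	2	0	7	4	4	5	1	11	105	25498	0.41
O. sativa	73	37	7	6	0	0	4	3	4	9	22	10	175	35825	0.49
Z. mays	30	15	3	2	0	0	4	2	1	9	2	3	71	39591	0.18
P. patens	21	0	3	3	3	2	9	3	0	6	0	4	54	35398	0.15
E. siliculosus													339	16256	2.08
G. max	48	30	13	3	2	4	12	7	13	2	1	27	162	55897	0.29
S. lycopersicum													130	33952	0.38
C. baccatum	42	33	2	2	1	1	1	1	0	0	0	4	87	35874	0.24
C. annuum	45	29	2	2	1	1	0	1	1	0	0	3	85	35884	0.24
C. chinense	62	26	2	1	1	1	1	0	0	0	0	2	96	35009	0.27
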