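name	pattern
WBOXATNPR1	TTGAC
ASF1MOTIFCAMV	TGACG
GCCCORE	GCCGCC
SEBFCONSSTPR10A	YTGTCWC
IBOX	GATAAG
-10PEHVPSBD	TATTCT
TBOXATGAPB	ACTTTG
INRNTPSADB	YTCANTYY
GT1CONSENSUS	GRWAAW
MYBCORE	CNGTTR
MYCATERD1	CATGTG
MYCATRD22	CACATG
MYBATRD22	CTAACCA
MYB2AT	TAACTG
MYB1AT	WAACCA
ABRELATERD1	ACGTG
WRKY71OS	TGAC
GATABOX	GATA
DOFCOREZM	AAAG
ARR1AT	NGATT
GAREAT	TAACAAR
PYRIMIDINEBOXOSRAMY1A	CCTTTT
CACTFTPPCA1	YACT
EBOXBNNAPA	CANNTG
ROOTMOTIFTAPOX1	ATATT
POLLEN1LELAT52	AGAAA
GTGANTG10	GTGA
ANAERO1CONSENSUS	AAACAAA
CAATBOX1	CAAT
TATABOX5	TTATTT
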