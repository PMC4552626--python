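gene	description	avsd_meth_diff	vsd_meth_diff	log2fc
PCDHGB1	Protocadherin gamma subfamily B, 1	-44.44	-43.88	-1.59
PFKFB2	6-phosphofructo-2-kinase	29.67	92.29	-1.6
TRPC3	Transient receptor potential cation channel	-26.14	-43.45	-0.86
WDR27	WD repeat domain 27	-29.23	-27.91	-1
YOD1	YOD1 deubiquitinase	29.66	92.28	-1.4
CBFA2T3	Core-binding factor, runt domain	26.46	-26.06	0.09
CSRNP2	Cysteine-serine-rich nuclear protein 2	26.21	55.58	-1.5
DIP2C	DIP2 disco-interacting protein 2 homolog C	-34.88	-25.81	-1.32
EPHA8	EPH receptor A8	30.86	-33.74	1
LY9	Lymphocyte antigen 9	-55.7	34.54	NA
NFATC1	Nuclear factor of activated T-cells	-30.08	-25.81	-1
SLC9A3R2	Solute carrier family 9	-38.78	32.26	-1.8
TNNT3	Troponin T type 3	-36.11	-59.85	0
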