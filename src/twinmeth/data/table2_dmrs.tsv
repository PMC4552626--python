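chrom	start	end	meth_diff	gene	description
chr1	24016268	24019268	68.33	RPL11	Ribosomal protein L11
chr1	115123265	115126265	33.29	BCAS2	Breast carcinoma amplified sequence 2
chr1	115123265	115126265	33.29	DENND2C	DENN/MADD domain containing 2C
chr1	155909479	155912479	26.17	RXFP4	Relaxin/insulin-like family peptide receptor 4
chr2	26780566	26783566	26.11	OTOF	Otoferlin
chr2	176962529	176965529	55.30	HOXD12	Homeobox D12
chr2	176979491	176982491	62.16	HOXD10	Homeobox D10
chr2	177026804	177029804	35.19	HOXD3	Homeobox D3
chr3	183722125	183725125	-33.80	ABCC5	ATP-binding cassette, sub-family C
chr3	195941382	195944382	25.26	SLC51A	Solute carrier family 51
chr5	79550898	79553898	49.96	SERINC5	Serine incorporator 5
chr5	140798536	140801536	25.12	PCDHGA1	Protocadherin gamma subfamily A
chr5	179498118	179501118	-26.77	RNF130	Ring finger protein 130
chr7	129140319	129143319	43.34	SMKR1	Small lysine-rich protein 1
chr7	148934741	148937741	47.16	ZNF212	Zinc finger protein 212
chr8	104381742	104384742	31.30	CTHRC1	Collagen triple helix repeat containing 1
chr9	35904188	35907188	-25.15	HRCT1	Histidine rich carboxyl terminus 1
chr9	131682561	131685561	-39.51	PHYHD1	Phytanoyl-coa dioxygenase domain 1
chr9	132403448	132406448	40.11	ASB6	Ankyrin repeat and SOCS box containing 6
chr9	133882503	133885503	30.65	LAMC3	Laminin, gamma 3
chr10	100027007	100030007	41.49	LOXL4	Lysyl oxidase-like 4
chr11	17564963	17567963	41.50	USH1C	Usher syndrome 1C
chr15	74464086	74467086	38.36	ISLR	Immunoglobulin superfamily leucine-rich
chr15	91471409	91474409	39.87	HDDC3	HD domain containing 3
chr16	68266402	68269402	33.39	ESRP2	Epithelial splicing regulatory protein 2
chr16	73124247	73127247	31.28	HCCAT5	Hepatocellular carcinoma transcript 5
chr16	75527926	75530926	52.13	CHST6	Carbohydrate
chr17	8868029	8871029	25.36	PIK3R5	Phosphoinositide-3-kinase
chr17	46671319	46674319	45.27	HOXB5	Homeobox B5
chr17	46671319	46674319	45.27	HOXB6	Homeobox B6
chr19	4866780	4869780	44.22	PLIN3	Perilipin 3
chr19	36247043	36250043	27.12	HSPB6	Heat shock protein B6
chr19	46848250	46851250	25.66	PPP5C	Protein phosphatase 5, catalytic subunit
chr19	55585220	55588220	30.81	EPS8L1	EPS8-like 1
chr20	30223690	30226690	-26.72	COX4I2	Cytochrome c oxidase subunit IV isoform 2
chr20	45279100	45282100	25.21	SLC13A3	Solute carrier family 13
chr21	46338949	46341949	55.20	ITGB2	Integrin, beta 2
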