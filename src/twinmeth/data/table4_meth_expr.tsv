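gene	fibroblast_meth_diff	fibroblast_log2fc	ipsc_meth_diff	ipsc_log2fc
HOXD3	35.2	-0.80	36.4	-5.7
HOXD10	62.16	-2.84	-6.8	-1.02
HOXB5	45.3	-0.32	59	-7
HOXB6	45.3	-1.85	59	-5
CTHRC1	31.3	-0.30	-53.4	0.43
USH1C	41.5	0.0	-5	0.4
HOXD12	60.58	3.12	77.92	-0.03
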