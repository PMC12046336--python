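snp	population	vaf	n_individuals
rs11203152	EUR	0.10	7718
rs11203152	AFR	0.066	4359
rs11203152	EAS	0.001	780
rs848048	EUR	0.49	7718
rs848048	AFR	0.23	4359
rs848048	EAS	0.46	780
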