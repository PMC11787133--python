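TLS_12_CHEMOKINE	12-chemokine TLS signature	CCL2	CCL3	CCL4	CCL5	CCL8	CCL18	CCL19	CCL21	CXCL9	CXCL10	CXCL11	CXCL13
CXCL13	single-gene follicular chemokine	CXCL13
PLASMA_CELL	plasma cell signature	MZB1	CD79A	DERL3	TNFRSF17	IGHG1	JCHAIN	XBP1
TFH	T follicular helper cell signature	CXCL13	CD200	FBLN7	ICOS	PDCD1	SGPP2	SH2D1A	TIGIT	BTLA
TH1	T helper 1 cell signature	TBX21	IFNG	STAT4	IL12RB2	CCR5	CXCR3	IL2
TH1_B_CELL	combined Th1 and B cell signature	CD19	MS4A1	CD79B	TBX21	IFNG	STAT1	CCL19	CCL21
TLS_IMPRINT	TLS imprint signature	CD79B	CD1D	CCR6	LAT	SKAP1	CETP	EIF1AY	RBP5	PTGDS
CYT	cytolytic activity genes	GZMA	PRF1
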