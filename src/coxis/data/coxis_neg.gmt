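COXIS_CI	cancer-inhibitory inflammatory genes	CCL5	CXCL9	CXCL10	CXCL11	IL12A	IL12B	IFNG	CD8A	CD8B	GZMA	GZMB	EOMES	PRF1	STAT1	TBX21
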