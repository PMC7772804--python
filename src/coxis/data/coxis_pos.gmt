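COXIS_CP	cancer-promoting inflammatory genes	VEGFA	CCL2	IL8	CXCL1	CXCL2	CSF3	IL6	IL1B	IL1A
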