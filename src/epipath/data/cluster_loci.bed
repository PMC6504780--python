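7	999999	1300000	EXOC4
1	1999999	2080000	1q23.1
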