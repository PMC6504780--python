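tob1Pathway	Role of Tob in T-cell activation	TOB1	TOB2	IFNG	IL2	IL2RA	IL4	SMAD3	SMAD4	TGFB1	TGFB2	TGFB3	TGFBR1	TGFBR2	TGFBR3	CD3D	CD3E	CD3G	CD247	CD28
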