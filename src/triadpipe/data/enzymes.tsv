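name	recognition	cut_offset
Fnu4HI	GCNGC	2
EcoRI	GAATTC	1
HinfI	GANTC	1
HaeIII	GGCC	2
MspI	CCGG	1
DdeI	CTNAG	1
AluI	AGCT	2
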