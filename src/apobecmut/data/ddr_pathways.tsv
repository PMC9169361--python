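pathway	gene
NER	ERCC2
NER	EP300
NER	POLE
NER	INO80
HRR	ATM
HRR	BRIP1
FA	ATR
MMR	SETD2
NHEJ	PRKDC
TLS	REV3L
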