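enzyme	motif	efficiency
SpCas9	NGG	high
SpCas9	NAG	high
SpCas9_VQR	NGAN	high
SpCas9_VQR	NGNG	high
SpCas9_EQR	NGAG	high
SpCas9_EQR	TGCG	high
SpCas9_VRER	GGCG	high
SaCas9	NNGRRT	high
AsCpf1	TTTN	high
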