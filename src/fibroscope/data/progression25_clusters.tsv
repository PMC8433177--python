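cluster	gene
2	CCL20
2	CFAP221
2	DTNA
2	DUSP8
2	IL32
2	ITGBL1
2	STMN2
2	TNFRSF12A
3	COL1A1
3	COL1A2
3	LTBP2
3	PDGFA
3	RGS4
3	THY1
5	AKR1B10
5	CLIC6
5	TYMS
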