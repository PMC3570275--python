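a	b	source	location_a	location_b
A2M	APOE	toy	extracellular	extracellular
APOE	APP	toy	extracellular	membrane
ANG	ACTC1	toy	extracellular	cytoplasm
ANG	ACTN2	toy	extracellular	cytoplasm
ANG	ATP6AP1	toy	extracellular	membrane
ANG	PTEN	toy	extracellular	cytoplasm
ANG	RNH1	toy	extracellular	cytoplasm
ANG	TDGF1	toy	extracellular	membrane
ANG	TNFSF8	toy	extracellular	membrane
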