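circRNA	miRNA	gene	pathway
hsa-CYP2U1_0001	miR-4722-5p	PSMD11	Immune system
hsa-SFMBT2_0001	miR-4722-5p	PSMD11	Immune system
hsa-ARID1A_0001	miR-766-5p	PSMD11	Immune system
hsa-CYP2U1_0001	miR-766-5p	PSMD11	Immune system
hsa-PAPPA_0016	miR-766-5p	PSMD11	Immune system
hsa-KMT2E-AS1_0001	miR-766-5p	PSMD11	Immune system
hsa-SFMBT2_0001	miR-766-5p	PSMD11	Immune system
hsa-ATP2C1_0001	miR-766-5p	PSMD11	Immune system
hsa-PAPPA2_0005	miR-942-5p	CREBBP	ASD pathways
hsa-CYP2U1_0001	miR-942-5p	CREBBP	ASD pathways
hsa-ERC1_0001	miR-942-5p	CREBBP	ASD pathways
hsa-PAPPA2_0005	miR-6875-3p	TBL1X	ASD pathways
hsa-PAPPA_0016	miR-6875-3p	TBL1X	ASD pathways
hsa-SCLT1_0001	miR-6875-3p	TBL1X	ASD pathways
hsa-ERC1_0001	miR-6875-3p	TBL1X	ASD pathways
hsa-PAPPA2_0005	miR-4738-3p	SRSF11	Transcription
hsa-MAN1A2_0001	miR-4738-3p	SRSF11	Transcription
hsa-PAPPA2_0005	miR-129-5p	NOTCH1	ASD pathways
hsa-SCLT1_0001	miR-129-5p	NOTCH1	ASD pathways
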