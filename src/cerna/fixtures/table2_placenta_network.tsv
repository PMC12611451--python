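circRNA	miRNA	gene	pathway
hsa-MAN1A2_0008	miR-4722-5p	PSMD11	Immune system
hsa-ZKSCAN1_0001	miR-4722-5p	PSMD11	Immune system
hsa-MAN1A2_0008	miR-942-5p	CREBBP	ASD pathways
hsa-MAN1A2_0003	miR-942-5p	CREBBP	ASD pathways
hsa-MAN1A2_0002	miR-942-5p	CREBBP	ASD pathways
hsa-FBXW7_0005	miR-942-5p	CREBBP	ASD pathways
hsa-ZNF609_0001	miR-942-5p	CREBBP	ASD pathways
hsa-CDYL_0005	miR-942-5p	CREBBP	ASD pathways
hsa-HIPK3_0001	miR-942-5p	CREBBP	ASD pathways
hsa-MAN1A2_0008	miR-6875-3p	TBL1X	ASD pathways
hsa-MAN1A2_0003	miR-6875-3p	TBL1X	ASD pathways
hsa-MAN1A2_0002	miR-6875-3p	TBL1X	ASD pathways
hsa-FBXW7_0005	miR-6875-3p	TBL1X	ASD pathways
hsa-ZNF609_0001	miR-6875-3p	TBL1X	ASD pathways
hsa-CDYL_0005	miR-6875-3p	TBL1X	ASD pathways
hsa-MAN1A2_0008	miR-6832-3p	SRSF11	Transcription
hsa-MAN1A2_0003	miR-6832-3p	SRSF11	Transcription
hsa-MAN1A2_0002	miR-6832-3p	SRSF11	Transcription
hsa-CDYL_0005	miR-6832-3p	SRSF11	Transcription
hsa-MAN1A2_0008	mir-623	NOTCH1	ASD pathways
hsa-MAN1A2_0003	mir-623	NOTCH1	ASD pathways
hsa-MAN1A2_0002	mir-623	NOTCH1	ASD pathways
hsa-FBXW7_0005	mir-623	NOTCH1	ASD pathways
hsa-ZNF609_0001	mir-623	NOTCH1	ASD pathways
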