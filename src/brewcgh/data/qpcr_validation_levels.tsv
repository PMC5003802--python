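# qRT-PCR relative transcript levels for four dosage-variable genes in four
# brewing strains, normalized to the ALG9 housekeeping gene and expressed
# relative to the laboratory reference strain BY4741 (mean +/- SD of >= 3
# independent experiments). Values of ~4e-4 are non-detects: the transcript
# (and the gene) is absent from that strain.
strain	gene	level	sd
4	FIT3	0.0180	0.0010
4	MAL13	1.0668	0.0693
4	AAD10	0.2257	0.0417
4	ALD2	0.4143	0.0423
6	FIT3	0.0004	0.0001
6	MAL13	0.9243	0.0067
6	AAD10	0.0003	0.0001
6	ALD2	0.5779	0.0418
8	FIT3	0.0558	0.0021
8	MAL13	0.0004	0.0001
8	AAD10	0.4108	0.0084
8	ALD2	0.5524	0.0461
9	FIT3	0.0264	0.0018
9	MAL13	0.9239	0.0435
9	AAD10	1.3551	0.0274
9	ALD2	0.0004	0.0003
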