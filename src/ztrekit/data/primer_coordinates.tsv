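name	reference	start	end	coordinate_system	note
emsa_probe	SLC30A5_promoter	-156	46	promoter_no_zero	EMSA probe window around the TSS
ztre_element	SLC30A5_promoter	-91	-76	promoter_no_zero	full ZTRE element (left half + 3 nt spacer + right half)
ztre_deletion	SLC30A5_promoter	-91	-84	promoter_no_zero	8-base deletion removing the 5' side of the ZTRE
ztre_competitor	SLC30A5_promoter	-124	-75	promoter_no_zero	50-bp double-stranded competitor oligonucleotide
qpcr_18s_amplicon	NR_003286	92	184	one_based	93-bp 18S rRNA qPCR amplicon
qpcr_45s_forward	NR_046235	312	330	one_based	45S rRNA forward primer
qpcr_45s_reverse	NR_046235	427	446	one_based	45S rRNA reverse primer (annotated 446..427)
qpcr_actb_forward	NM_001101	1359	1378	one_based	beta-actin forward primer
qpcr_actb_reverse	NM_001101	1433	1455	one_based	beta-actin reverse primer (annotated 1455..1433)
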