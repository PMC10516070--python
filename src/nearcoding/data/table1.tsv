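chrom	pos	ref	alt	gene	transcript	region_classes	deep_intronic	spliceai_max	cadd_phred	phylop	utr_effect
chr1	244051269	C	T	ZBTB18	ENST00000358704	promoter	0			7.426	-
chr1	42958757	C	T	SLC2A1	ENST00000426263	five_utr	0				uAUG_gain:outOfFrame_oORF:strong
chr2	189580684	A	C	SLC40A1	ENST00000261024	five_utr	0			8.189	-
chr3	9397977	G	A	SETD5	ENST00000402198	five_utr_intron	0	0.97			-
chr5	36953600	T	A	NIPBL	ENST00000282516	five_utr_intron	0	0.24			-
chr5	88823813	G	A	MEF2C	ENST00000504921	five_utr	0				uAUG_gain:inFrame_oORF:moderate
chr11	31806843	C	T	PAX6	ENST00000640368	five_utr_intron	0	0.56			-
chr11	31806925	CT	C	PAX6	ENST00000640368	five_utr_intron	0	0.65			-
chr11	119341417	C	A	MFRP	ENST00000619721	three_utr	0	0.56			-
chr17	8382316	T	C	RPL26	ENST00000648839	five_utr_intron	0	0.97	35		-
chr20	58909653	A	G	GNAS	ENST00000371075	three_utr_intron	1	0.67			-
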