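locus	gene_type	group	label	n_genes	n_alleles
IGH	V	IGHV1	F	11	13
IGH	V	IGHV1	P	14	18
IGH	V	IGHV2	F	5	6
IGH	V	IGHV2	ORF	1	1
IGH	V	IGHV2	P	1	1
IGH	V	IGHV3	F	39	62
IGH	V	IGHV3	ORF	1	2
IGH	V	IGHV3	P	34	52
IGH	V	IGHV3	FO	2	4
IGH	V	IGHV3	FP	2	4
IGH	V	IGHV4	F	19	25
IGH	V	IGHV4	P	3	4
IGH	V	IGHV4	FP	3	6
IGH	V	IGHV5	F	2	4
IGH	V	IGHV5	P	1	2
IGH	V	IGHV6	F	1	1
IGH	V	IGHV7	F	2	3
IGH	V	IGHV7	P	12	14
IGH	V	IGHV8	P	2	4
IGH	V	IGHV(I)	P	6	9
IGH	V	IGHV(II)	P	35	53
IGH	V	IGHV(III)	P	32	48
IGH	D	IGHD1	F	9	11
IGH	D	IGHD2	F	7	8
IGH	D	IGHD3	F	7	7
IGH	D	IGHD4	F	7	7
IGH	D	IGHD5	F	6	7
IGH	D	IGHD5	ORF	1	1
IGH	D	IGHD6	F	7	7
IGH	D	IGHD7	F	1	1
IGH	J	IGHJ1	F	1	2
IGH	J	IGHJ2	F	1	1
IGH	J	IGHJ3	F	1	1
IGH	J	IGHJ4	F	1	1
IGH	J	IGHJ5	F	2	4
IGH	J	IGHJ6	F	1	1
IGH	C	IGHM	FP	1	3
IGH	C	IGHD	F	1	3
IGH	C	IGHG	F	3	16
IGH	C	IGHG	FP	1	7
IGH	C	IGHE	F	1	1
IGH	C	IGHA	F	1	22
IGL	V	IGLV1	F	14	19
IGL	V	IGLV1	P	5	12
IGL	V	IGLV2	F	11	21
IGL	V	IGLV2	P	5	6
IGL	V	IGLV3	F	25	35
IGL	V	IGLV3	ORF	1	3
IGL	V	IGLV3	P	16	23
IGL	V	IGLV3	FP	1	2
IGL	V	IGLV4	F	3	5
IGL	V	IGLV4	ORF	1	2
IGL	V	IGLV4	P	1	2
IGL	V	IGLV5	F	8	12
IGL	V	IGLV5	P	8	15
IGL	V	IGLV6	F	3	6
IGL	V	IGLV6	P	2	2
IGL	V	IGLV7	F	4	5
IGL	V	IGLV7	P	5	5
IGL	V	IGLV8	F	1	2
IGL	V	IGLV9	F	1	1
IGL	V	IGLV10	F	1	1
IGL	V	IGLV10	P	1	1
IGL	V	IGLV11	F	1	1
IGL	V	IGLV(I)	P	18	24
IGL	V	IGLV(II)	P	4	7
IGL	V	IGLV(III)	P	3	4
IGL	V	IGLV(IV)	P	5	8
IGL	V	IGLV(V)	P	1	1
IGL	J	IGLJ1	F	1	1
IGL	J	IGLJ2	F	1	1
IGL	J	IGLJ2A	F	1	1
IGL	J	IGLJ3	F	1	1
IGL	J	IGLJ4	ORF	1	1
IGL	J	IGLJ5	F	1	1
IGL	J	IGLJ6	F	1	1
IGL	J	IGLJ7	FO	1	2
IGL	C	IGLC1	F	1	1
IGL	C	IGLC2	F	1	2
IGL	C	IGLC2A	F	1	1
IGL	C	IGLC3	F	1	1
IGL	C	IGLC4	P	1	2
IGL	C	IGLC5	P	1	2
IGL	C	IGLC6	F	1	2
IGL	C	IGLC7	F	1	2
IGK	V	IGKV1	F	39	56
IGK	V	IGKV1	ORF	1	1
IGK	V	IGKV1	P	13	16
IGK	V	IGKV1	FP	3	7
IGK	V	IGKV2	F	21	28
IGK	V	IGKV2	ORF	3	3
IGK	V	IGKV2	P	21	29
IGK	V	IGKV2	FO	1	2
IGK	V	IGKV2	FP	4	10
IGK	V	IGKV3	F	11	25
IGK	V	IGKV3	ORF	1	1
IGK	V	IGKV3	P	7	8
IGK	V	IGKV4	F	1	2
IGK	V	IGKV4	ORF	1	1
IGK	V	IGKV4	P	2	4
IGK	V	IGKV5	F	2	3
IGK	V	IGKV6	F	2	2
IGK	V	IGKV6	P	2	2
IGK	V	IGKV7	FP	1	2
IGK	V	IGKV(II)	P	2	4
IGK	J	IGKJ1	F	1	1
IGK	J	IGKJ2	F	1	1
IGK	J	IGKJ3	F	1	1
IGK	J	IGKJ4	F	1	1
IGK	J	IGKJ5	F	1	1
IGK	C	IGKC	F	1	2
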