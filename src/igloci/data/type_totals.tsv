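locus	gene_type	genes	alleles
IGH	V	228	336
IGH	D	45	49
IGH	J	7	10
IGH	C	8	52
IGL	V	149	225
IGL	J	8	9
IGL	C	8	13
IGK	V	138	206
IGK	J	5	5
IGK	C	1	2
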