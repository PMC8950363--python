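locus	subgroup	lengths	f	orf	inframe_p
IGH	IGHV1	[8.8.2]	11	0	3
IGH	IGHV1	[8.8.3]	0	0	1
IGH	IGHV2	[10.7.3]	5	1	0
IGH	IGHV3	[8.6.2]	2	0	0
IGH	IGHV3	[8.7.2]	7	0	0
IGH	IGHV3	[8.7.3]	0	1	0
IGH	IGHV3	[8.8.0]	0	0	1
IGH	IGHV3	[8.8.1]	0	0	1
IGH	IGHV3	[8.8.2]	17	0	5
IGH	IGHV3	[8.8.3]	2	0	3
IGH	IGHV3	[8.9.2]	1	0	0
IGH	IGHV3	[8.10.2]	12	1	2
IGH	IGHV4	[8.8.2]	8	0	0
IGH	IGHV4	[9.8.2]	11	0	0
IGH	IGHV4	[10.8.2]	2	0	0
IGH	IGHV5	[8.8.2]	2	0	1
IGH	IGHV6	[10.9.2]	1	0	0
IGH	IGHV7	[8.8.2]	2	0	7
IGL	IGLV1	[9.3.9]	2	0	2
IGL	IGLV1	[8.3.9]	12	0	0
IGL	IGLV2	[9.3.9]	11	0	1
IGL	IGLV3	[6.3.7]	5	0	0
IGL	IGLV3	[6.3.8]	1	0	0
IGL	IGLV3	[6.3.9]	18	1	1
IGL	IGLV3	[6.3.12]	1	0	0
IGL	IGLV4	[7.7.7]	2	0	0
IGL	IGLV4	[7.7.12]	1	1	0
IGL	IGLV5	[9.7.8]	7	0	1
IGL	IGLV5	[9.7.9]	2	0	1
IGL	IGLV6	[8.3.8]	3	0	0
IGL	IGLV7	[9.3.8]	4	0	3
IGL	IGLV8	[9.3.8]	1	0	0
IGL	IGLV9	[7.8.12]	1	0	0
IGL	IGLV10	[8.3.9]	1	0	0
IGL	IGLV11	[9.7.8]	1	0	0
IGK	IGKV1	[6.3.7]	42	1	3
IGK	IGKV2	[11.3.7]	19	2	10
IGK	IGKV2	[11.3.8]	0	0	2
IGK	IGKV2	[12.3.7]	5	1	0
IGK	IGKV3	[6.3.4]	0	0	4
IGK	IGKV3	[6.3.7]	11	1	0
IGK	IGKV3	[7.3.7]	0	0	1
IGK	IGKV4	[12.3.7]	1	1	1
IGK	IGKV5	[6.3.7]	2	0	0
IGK	IGKV6	[6.3.7]	2	0	1
IGK	IGKV7	[10.3.7]	0	0	1
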