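locus	chromosome	orientation	chrom_start	chrom_end	size_kb	n_v_localized	n_v_unlocalized	n_d	n_j	n_c	gaps
IGH	7	REV	167900000	169868564	1969	208	20	45	7	8	48631-48730;398207-449403
IGL	10	REV	29621424	30922134	1301	127	22	0	8	8
IGK	13	FWD	16784193	18140859	1357	110	28	0	5	1
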