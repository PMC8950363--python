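locus	genes	alleles
IGH	288	447
IGL	165	247
IGK	144	214
ALL	597	908
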