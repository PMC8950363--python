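locus	side	heptamer	nonamer
IGH	V-RS	cacagtg	acacaaacc
IGH	5'D-RS	cactgtg	ggtttttgt
IGH	3'D-RS	cacagtg	tcaaaaacc
IGH	J-RS	cactgtg|caatgtg	ggtttttgt
IGL	V-RS	cacagtg	acaaaaacc
IGL	J-RS	cacagtg	ggtttttgt
IGK	V-RS	cacagtg	acaaaaacc
IGK	J-RS	cactgtg	ggtttttgt
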