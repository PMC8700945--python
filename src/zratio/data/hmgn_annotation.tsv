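gene_symbol	entrez_id	locus
HMGN1	3150	21q22.2
HMGN2	3151	1p36.11
HMGN3	9324	6q14.1
HMGN4	10473	6p22.2
HMGN5	79366	Xq21.1
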