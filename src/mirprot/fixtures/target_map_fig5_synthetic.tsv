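mirna_id	gene_symbol	evidence
miR-432-5p	PAX8	high
miR-432-5p	CRYAB	moderate
miR-432-5p	ITGA2	moderate
miR-432-5p	CELF2	high
miR-432-5p	ARHGAP12	moderate
miR-432-5p	BST1	moderate
miR-432-5p	DECR2	high
miR-127-3p	PAX8	high
miR-127-3p	INA	moderate
miR-127-3p	NTM	moderate
miR-138-5p	PAX8	high
miR-138-5p	ALDH1A2	experimental
miR-138-5p	TPK1	moderate
miR-138-5p	MASTL	moderate
miR-138-5p	TUBB4A	high
miR-138-5p	FDXR	moderate
miR-138-5p	ROCK1	experimental
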