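gene_symbol	alias	cytoband	ratio
ARHGAP12	Rho GTPase Activating Protein 12	10p11.22	11.77340121
ARHGDIB	Rho GDP Dissociation Inhibitor Beta	12p12.3	0.086813615
ARRB1	Arrestin Beta 1	11q13.4	5.124634149
BST1	Bone Marrow Stromal Cell Antigen 1	4p15.32	6.122146871
CELF2	CUGBP Elav-like Family Member 2	10p14	13.84767274
COL5A1	Collagen Type V Alpha 1 Chain	9q34.3	0.112864701
CRABP2	Cellular Retinoic Acid Binding Protein 2	1q23.1	0.09458846
CRYAB	Crystallin Alpha B	11q23.1	17.53439428
DECR2	2,4-Dienoyl-CoA Reductase 2	16p13.3	9.463406179
FAM171A1	Family With Sequence Similarity 171 Member A1	10p13	6.197873721
FDXR	Ferredoxin Reductase	17q25.1	4.595277
IDI1	Isopentenyl-Diphosphate Delta Isomerase 1	10p15.3	0.156436427
INA	Internexin Neuronal Intermediate Filament Protein Alpha	10q24.33	7.346539312
ITGA2	Integrin Subunit Alpha 2	5q11.2	16.44875121
KIN	Kin17 DNA and RNA Binding Protein	10p14	11.27786487
MASTL	Microtubule Associated Serine/Threonine Kinase Like	10p12.1	6.20270082
NMT2	N-myristoyltransferase 2	10p13	4.073197008
NTM	Neurotrimin	11q25	7.970555423
PAAF1	Proteasomal ATPase Associated Factor 1	11q13.4	4.390010657
PATL1	PAT1 Homolog 1, Processing Body mRNA Decay Factor	11q12.1	5.037787567
RBP1	Retinol Binding Protein 1	3q23	0.072160245
ROCK1	Rho Associated Coiled-Coil Containing Protein Kinase 1	18q11.1	7.346539312
SEC14L2	SEC14 Like Lipid Binding 2	22q12.2	0.10067807
SLC1A4	Solute Carrier Family 1 Member 4	2p14	0.235645725
TGFBI	Transforming Growth Factor Beta 1	19q13.2	0.113836913
TMEM123	Transmembrane Protein 123	11q22.2	6.71872719
TPK1	Thiamin Pyrophosphokinase 1	7q35	4.34870065
TUBB4A	Tubulin Beta 4A Class IVa	19p13.3	4.021247785
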