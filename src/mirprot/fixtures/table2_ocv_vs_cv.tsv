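mirna_id	cytoband	fold_change	fdr_p	fragile_site
hsa-miR-4632-5p	1p36.22	2.6	0.6116	FRA1A (1p36)
miR-34a-5p	1p36.22	2.08	0.64	FRA1A (1p36)
miR-128-3p	2q21.3	-2.11	0.4371	FRA2F (2q21.3)
miR-378a-3p	5q32	7.66	0.0046	FRA5C (5q31.1)
miR-584-5p	5q32	2.67	0.7337	FRA5C (5q31.1)
miR-378a-5p	5q32	2.17	0.4959	FRA5C (5q31.1)
miR-146a-5p	5q33.3	11.43	0.0899	FRA5C (5q31.1)
miR-4640-5p	6p21.33	3.72	0.4959	FRA6C (6p22.2)
miR-589-3p	7p22.1	-2.2	0.8838	FRA7B (7p22)
miR-182-5p	7q32.2	-3.58	0.4959	FRA7G (7q31.2); FRA7H (7q32.3)
miR-6850-5p	8q24.3	2.0	0.8777	FRA8D (8q24.3)
let7e-5p	9q22.32	-3.92	0.0000145	FRA9D (9q22.1)
miR-455-3p	9q32	4.77	0.0004	FRA9E (9q32)
miR-1343-5p	11p13	2.31	0.6116	FRA11E (11p13)
miR-210-3p	11p15.5	-2.19	0.1089	FRA11C (11p15.1)
miR-139-5p	11q13.4	8.53	0.0004	FRA11H (11q13)
miR-125a-5p	11q24.1	-4.65	0.0000867	FRA11G (11q23.3)
miR-615-3p	12q13.13	3.55	0.0263	N/A
miR-17-5p	13q31.3	4.75	0.3337	FRA13D (13q32)
miR-18a-5p	13q31.3	3.9	0.2576	FRA13D (13q32)
miR-18a-3p	13q31.3	3.79	0.1212	FRA13D (13q32)
miR-92a-3p	13q31.3	2.48	0.0046	FRA13D (13q32)
miR-127-3p	14q32.2	-11.76	0.0000145	FRA14C (14q24.1)
miR-432-5p	14q32.2	-11.75	0.0001	FRA14C (14q24.1)
miR-433-3p	14q32.2	-2.62	0.5388	FRA14C (14q24.1)
miR-134-5p	14q32.31	-6.06	0.6116	FRA14C (14q24.1)
miR-409-3p	14q32.31	-6.04	0.0004	FRA14C (14q24.1)
miR-382-5p	14q32.31	-3.22	0.1845	FRA14C (14q24.1)
miR-370-3p	14q32.31	-3.13	0.1777	FRA14C (14q24.1)
miR-485-3p	14q32.31	-2.22	0.5816	FRA14C (14q24.1)
miR-487b-3p	14q32.31	-2.04	0.8716	FRA14C (14q24.1)
miR-3180	16p13.11	2.82	0.8777	N/A
miR-744-5p	17p12	-2.21	0.0397	N/A
miR-6776-5p	17p13.3	2.72	0.8777	N/A
hsa-miR-6779-5p	17q12	3.24	0.0456	N/A
miR-27b-3p	19p13.12	-2.31	0.6552	N/A
miR-23b-3p	19p13.12	-2.14	0.2479	N/A
miR-769-5p	19q13.32	-2.62	0.6116	N/A
hsa-miR-99b-5p	19q13.41	-4.88	0.0046	N/A
miR-125a-3p	19q13.41	-3.51	0.2479	N/A
miR-296-3p	20q13.32	3.11	0.0046	N/A
miR-941	20q13.33	2.87	0.8772	N/A
miR-99b-3p	21q21.1	-4.18	0.0004	N/A
miR-500a-5p	Xp11.23	2.03	0.8428	N/A
miR-424-3p	Xq26.3	5.6	0.131	FRAXD (Xq27.2)
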