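mirna_id	cytoband	fold_change	fdr_p	fragile_site
miR-34a-5p	1p36.22	6.85	0.0289	FRA1A (1p36)
miR-138-5p	3p21.31	-16.25	0.00000189	FRA3A (3p24.2); FRA3B (3p14.2)
hsa-miR-7110-5p	3q21.1	2.29	0.499	FRA3D (3q25)
miR-145-5p	5q32	-2.38	0.454	FRA5C (5q31.1)
miR-146a-5p	5q33.3	10.26	0.3107	FRA5C (5q31.1)
mir-182-5p	7q32.2	-9.19	0.0302	FRA7G (7q31.2); FRA7H (7q32.3)
miR-31-5p	9p21.3	2.32	0.0633	N/A
miR-1296-5p	10q21.3	-5.42	0.088	FRA10D (10q22.1)
miR-210-3p	11p15.5	-2.09	0.0126	FRA11C (11p15.1)
miR-708-5p	11q14.1	3.44	0.0066	FRA11F (11q14.2)
miR-34c-3p	11q23.1	3.83	0.1913	FRA11G (11q23.3)
miR-125b-5p	11q24.1	2.45	0.4807	FRA11G (11q23.3)
miR-125b-1-3p	11q24.1	2.45	0.4807	FRA11G (11q23.3)
miR-615-3p	12q13.13	-15.09	0.000092	N/A
miR-17-3p	13q31.3	2.24	0.1641	FRA13D (13q32)
miR-127-3p	14q32.2	-111.69	0.00000003	FRA14C (14q24.1)
miR-432-5p	14q32.2	-97.87	0.00000009	FRA14C (14q24.1)
miR-433-3p	14q32.2	-22.41	0.00000703	FRA14C (14q24.1)
miR-493-3p	14q32.2	-11.59	0.0073	FRA14C (14q24.1)
miR-431-5p	14q32.2	-6.02	0.0648	FRA14C (14q24.1)
hsa-miR-770-5p	14q32.2	-2.45	0.2568	FRA14C (14q24.1)
miR-342-5p	14q32.2	-2.34	0.4192	FRA14C (14q24.1)
miR-409-3p	14q32.31	-49.16	0.00000034	FRA14C (14q24.1)
miR-382-5p	14q32.31	-37.07	0.0002	FRA14C (14q24.1)
miR-379-5p	14q32.31	-23.84	0.0000202	FRA14C (14q24.1)
miR-487b-3p	14q32.31	-22.55	0.0004	FRA14C (14q24.1)
miR-485-3p	14q32.31	-18.02	0.0003	FRA14C (14q24.1)
hsa-miR-654-5p	14q32.31	-9.37	0.0001	FRA14C (14q24.1)
hsa-miR-1185-1-3p	14q32.31	-8.64	0.0000973	FRA14C (14q24.1)
miR-485-5p	14q32.31	-5.98	0.0066	FRA14C (14q24.1)
miR-323a-5p	14q32.31	-5.85	0.0000546	FRA14C (14q24.1)
miR-134-5p	14q32.31	-3.58	0.2484	FRA14C (14q24.1)
miR-487a-5p	14q32.31	-3.04	0.4192	FRA14C (14q24.1)
miR-409-5p	14q32.31	-2.54	0.6136	FRA14C (14q24.1)
miR-329-3p	14q32.31	-2.52	0.2568	FRA14C (14q24.1)
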