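scale	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
hydropathy_kyte_doolittle	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
hydrophilicity_hopp_woods	-0.5	3.0	0.2	3.0	-1.0	0.2	3.0	0.0	-0.5	-1.8	-1.8	3.0	-1.3	-2.5	0.0	0.3	-0.4	-3.4	-2.3	-1.5
hydrophobicity_eisenberg	0.62	-2.53	-0.78	-0.9	0.29	-0.85	-0.74	0.48	-0.4	1.38	1.06	-1.5	0.64	1.19	0.12	-0.18	-0.05	0.81	0.26	1.08
hydrophobicity_fauchere_pliska	0.31	-1.01	-0.6	-0.77	1.54	-0.22	-0.64	0.0	0.13	1.8	1.7	-0.99	1.23	1.79	0.72	-0.04	0.26	2.25	0.96	1.22
hydrophobicity_janin	0.3	-1.4	-0.5	-0.6	0.9	-0.7	-0.7	0.3	-0.1	0.7	0.5	-1.8	0.4	0.5	-0.3	-0.1	-0.2	0.3	-0.4	0.6
mean_area_buried_rose	0.74	0.64	0.63	0.62	0.91	0.62	0.62	0.72	0.78	0.88	0.85	0.52	0.85	0.88	0.64	0.66	0.7	0.85	0.76	0.86
polarity_grantham	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
polarity_zimmerman	0.0	52.0	3.38	49.7	1.48	3.53	49.9	0.0	51.6	0.13	0.13	49.5	1.43	0.35	1.58	1.67	1.66	2.1	1.61	0.13
bulkiness_zimmerman	11.5	14.28	12.82	11.68	13.46	14.45	13.57	3.4	13.69	21.4	21.4	15.71	16.25	19.8	17.43	9.47	15.77	21.67	18.03	21.57
isoelectric_point_zimmerman	6.0	10.76	5.41	2.77	5.05	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.3	5.68	5.6	5.89	5.66	5.96
residue_molecular_weight	71.08	156.19	114.1	115.09	103.14	128.13	129.12	57.05	137.14	113.16	113.16	128.17	131.19	147.18	97.12	87.08	101.1	186.21	163.18	99.13
number_of_codons	4	6	2	2	2	2	2	4	2	3	6	2	1	2	4	6	4	1	2	4
alpha_helix_chou_fasman	1.42	0.98	0.67	1.01	0.7	1.11	1.51	0.57	1.0	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
beta_sheet_chou_fasman	0.83	0.93	0.89	0.54	1.19	1.1	0.37	0.75	0.87	1.6	1.3	0.74	1.05	1.38	0.55	0.75	1.19	1.37	1.47	1.7
beta_turn_chou_fasman	0.66	0.95	1.56	1.46	1.19	0.98	0.74	1.56	0.95	0.47	0.59	1.01	0.6	0.6	1.52	1.43	0.96	0.96	1.14	0.5
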