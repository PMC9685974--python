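gene	transcript	hgvs_c	pos	ref	alt	consequence	cadd	acmg	n_patients	sg_alt_alleles	af_case_sg	af_case_dbgap	af_gnomad_eas	af_sg10k	region_flags	review_pass	sg_af_note	or_sg_gnomad	padj_sg_gnomad	or_sg_sg10k	padj_sg_sg10k	or_dbgap_gnomad	padj_dbgap_gnomad	or_dbgap_sg10k	padj_dbgap_sg10k
KMT2C	NM_170606.3	c.C2689T	2689	C	T	stopgain	39.0	pathogenic	7	7	1.21	0.11	0.02		repetitive			72.88	1.9e-08			6.40	0.21		
KMT2C	NM_170606.3	c.C2710T	2710	C	T	stopgain	37.0	pathogenic	28	28	4.83	2.37	0.20		repetitive			25.25	1.6e-23			12.07	4.6e-14		
RNF43	NM_001305545.1	c.C311T	311	C	T	nonsynonymous_snv	24.0	benign	7	7	1.21	17.81	0.06	1.64		true		19.99	2.7e-06	0.73	0.58	351.43	4.5e-206	12.99	7e-100
RNF43	NM_001305545.1	c.G1589C	1589	G	C	nonsynonymous_snv	26.5	uncertain	3	3	0.52		0.00	1.01		true		Inf	5.3e-05	0.51	0.48				
RNF43	NM_001305545.1	c.G647A	647	G	A	nonsynonymous_snv	25.4	benign	11	11	1.90	8.76	0.03	1.33		true		71.69	2.3e-12	1.43	0.36	355.70	3.3e-93	7.11	1.1e-34
GPRIN2	NM_014696.4	c.C983G	983	C	G	nonsynonymous_snv	23.1	benign	17	17	2.93	20.92	0.10			true		30.03	5.4e-16			263.13	1e-243		
MUC4	NM_018406.7	c.G8461A	8461	G	A	nonsynonymous_snv	22.1	uncertain	16	21	3.60		0.00	0.04	repetitive		af_rounding	Inf	1.7e-26	104.51	3e-23				
H3F3A	NM_002107.6	c.C344G	344	C	G	nonsynonymous_snv	28.8	uncertain	14	14	2.41	0.65	0.71			true		3.47	0.00027			0.91	1		
AKAP9	NM_005751.4	c.T3430C	3430	T	C	nonsynonymous_snv	20.5	uncertain	11	11	1.90		0.43	1.62		true		4.52	0.00016	1.18	0.68				
TPTE2	NM_199254.2	c.483delT	483	T	-	frameshift_deletion	22.0	uncertain	10	10	1.77		0.08	0.04	homopolymer,segmental_duplication	true	af_patient_mismatch	23.88	7.5e-09	48.20	1.1e-10				
HLA-B	NM_005514.8	c.A161G	161	A	G	nonsynonymous_snv	23.6	uncertain	9	9	1.55	5.71	0.30	1.05		true		5.32	0.00023	1.49	0.37	20.43	1e-40	5.71	2.9e-14
NRG1	NM_013962.2	c.G172A	172	G	A	nonsynonymous_snv	23.6	benign	9	9	1.55	33.33	0.06	3.40		true		25.36	9.4e-05	0.45	0.02	705.43	4.6e-05	14.20	0.02
ELN	NM_001278913.2	c.G1498C	1498	G	C	nonsynonymous_snv	23.2	benign	8	8	1.38	8.91	0.03	1.25		true		55.70	3.1e-09	1.10	0.76	387.67	7.6e-106	7.72	2.1e-38
ERBB3	NM_001982.3	c.A3355T	3355	A	T	nonsynonymous_snv	23.8	benign	8	8	1.38	11.51	0.11	1.60		true		13.27	3.4e-06	0.86	0.91	123.49	3.4e-123	7.98	1.3e-49
HLA-A	NM_001242758.1	c.268delA	268	A	-	frameshift_deletion	2.03	uncertain	8	8	1.38	0.21	0.04	0.94	polymorphic_locus			34.34	2.4e-08	1.47	0.36	5.28	0.087	0.23	0.028
HLA-A	NM_001242758.1	c.C791T	791	C	T	nonsynonymous_snv	25.6	uncertain	8	8	1.38		0.13	1.95	polymorphic_locus			10.66	1.2e-05	0.70	0.53				
HLA-A	NM_001242758.1	c.G1055T	1055	G	T	nonsynonymous_snv	23.6	uncertain	8	8	1.38	0.11	0.14	3.46	polymorphic_locus			10.30	1.5e-05	0.39	0.0075	0.79	1	0.03	3.5e-12
HLA-A	NM_001242758.1	c.G565A	565	G	A	nonsynonymous_snv	22.1	uncertain	8	8	1.38	0.11	0.15	7.04	polymorphic_locus			9.50	2.2e-05	0.18	1.9e-08	0.73	1	0.01	3.1e-24
HLA-A	NM_001242758.1	c.G684A	684	G	A	stopgain	37.0	uncertain	8	8	1.38		0.06	1.31	polymorphic_locus			25.19	1.2e-07	1.06	0.89				
HLA-A	NM_001242758.1	c.T547C	547	T	C	nonsynonymous_snv	24.4	uncertain	3	3	0.52	0.11	0.02	0.21	polymorphic_locus			34.04	0.00076	2.51	0.26	7.03	0.2	0.52	1
ROS1	NM_002944.2	c.C3326T	3326	C	T	nonsynonymous_snv	21.1	benign	8	9	1.55	7.83	0.27	1.64		true		5.81	0.00013	0.94	1	31.29	2.4e-64	5.09	9.5e-25
HLA-DRB1	NM_002124.3	c.118_122del	118	NNNNN	-	frameshift_deletion	24.7	uncertain	7	24	4.09	0.15	0.07	0.24	polymorphic_locus		af_rounding	59.12	1.5e-13	17.57	5.7e-10	2.03	0.48	0.60	1
HLA-DRB1	NM_002124.3	c.126_127insTTAAGTTT	126	-	TTAAGTTT	frameshift_insertion	24.6	uncertain	7	16	2.83		0.05	0.13	polymorphic_locus		af_rounding	54.73	1.4e-12	22.29	1.9e-10				
HLA-DRB1	NM_002124.3	c.C301T	301	C	T	nonsynonymous_snv	25.5	likely_benign	4	6	0.99	0.00	0.00	0.06	polymorphic_locus		af_rounding	Inf	5e-06	16.51	0.00023	0.00	1	0.00	1
NTRK1	NM_001012331.1	c.C1792T	1792	C	T	nonsynonymous_snv	27.8	benign	6	6	1.03	6.01	0.03	1.16		true		34.72	1.8e-06	0.89	1	212.31	1.3e-68	5.43	1.5e-20
NTRK1	NM_001012331.1	c.G1820T	1820	G	T	nonsynonymous_snv	22.0	benign	5	5	0.86	6.02	0.03	1.13		true		28.88	2.2e-05	0.76	0.76	212.73	1.3e-68	5.58	5.2e-21
CHIC2	NM_012110.4	c.G36T	36	G	T	nonsynonymous_snv	22.2	uncertain	5	5	0.86		0.03	0.37		true		28.44	2.2e-05	2.33	0.11				
CNTRL	NM_001330762.2	c.G1009A	1009	G	A	nonsynonymous_snv	21.9	uncertain	5	5	0.86	5.52	0.02	0.82		true		57.55	3.4e-06	1.05	0.86	385.11	2.9e-65	7.08	4.2e-23
ISX	NM_001303508.2	c.G248A	248	G	A	nonsynonymous_snv	34.0	uncertain	5	5	0.86	5.15	0.04	1.41		true		21.66	4.9e-05	0.61	0.46	135.30	1.9e-56	3.81	6.8e-13
MYO5A	NM_000259.3	c.A3960T	3960	A	T	nonsynonymous_snv	21.7	benign	5	5	0.86		0.01	0.19		true		84.79	1.8e-06	4.64	0.01				
TET2	NM_001127208.2	c.C1088T	1088	C	T	nonsynonymous_snv	23.3	uncertain	5	6	1.03	4.94	0.04	0.82		true		29.69	2.9e-06	1.26	0.57	147.52	1.2e-54	6.26	3e-19
BRD7	NM_001173984.3	c.A44C	44	A	C	nonsynonymous_snv	22.8	uncertain	4	4	0.80				segmental_duplication	true	af_patient_mismatch								
CBFA2T3	NM_005187.6	c.G308C	308	G	C	nonsynonymous_snv	22.5	benign	4	4	0.69	9.55	0.01	0.53		true		69.07	2.5e-05	1.31	0.62	1036.93	6.9e-118	19.97	1.8e-66
DCC	NM_005215.4	c.A3578G	3578	A	G	nonsynonymous_snv	23.1	uncertain	4	4	0.69		0.10	0.65		true		7.08	0.0065	1.06	0.85				
PTPRB	NM_001206971.3	c.C3412T	3412	C	T	nonsynonymous_snv	25.1	uncertain	4	4	0.69	2.15	0.01	0.44		true		67.61	2.6e-05	1.58	0.42	214.17	5.6e-25	5.01	6.8e-08
RNF213	NM_001256071.3	c.C12847A	12847	C	A	nonsynonymous_snv	23.1	benign	3	3	0.52	6.55	0.00	0.39		true		Inf	5.3e-05	1.32	0.58	Inf	4.5e-83	17.80	3.4e-44
RNF213	NM_001256071.3	c.C13945G	13945	C	G	nonsynonymous_snv	24.4	benign	4	4	0.69	8.37	0.00	0.53		true		Inf	2.7e-06	1.31	0.62	Inf	2.7e-106	17.22	2.5e-55
CLIP1	NM_001247997.1	c.C80T	80	C	T	nonsynonymous_snv	23.3	likely_benign	3	3	0.52	1.29	0.00	0.04		true		Inf	5.3e-05	14.11	0.0043	Inf	1.1e-16	35.48	5.3e-12
CUX1	NM_001202543.2	c.C3317T	3317	C	T	nonsynonymous_snv	24.8	uncertain	3	3	0.52		0.01	0.09		true		51.86	0.00038	5.75	0.03				
FBLN2	NM_001998.3	c.G2569T	2569	G	T	nonsynonymous_snv	29.0	uncertain	3	3	0.52	0.22	0.00	1.34		true		Inf	6.5e-05	0.38	0.13	Inf	0.0031	0.16	0.0011
GNAS	NM_016592.4	c.A266G	266	A	G	nonsynonymous_snv	23.8	uncertain	3	3	0.52		0.00	0.03		true		Inf	6.2e-05	16.06	0.0034				
MAF	NM_001031804.3	c.G655T	655	G	T	nonsynonymous_snv	22.2	uncertain	3	3	4.81		0.00		repetitive		af_patient_mismatch	Inf	3.4e-06						
MGA	NM_001080541.2	c.C1883A	1883	C	A	nonsynonymous_snv	25.8	uncertain	3	3	0.52	1.54	0.00	0.08		true		Inf	6.7e-05	6.19	0.026	Inf	7.9e-19	18.55	1.6e-11
MLLT1	NM_005934.4	c.G889A	889	G	A	nonsynonymous_snv	24.8	uncertain	3	3	0.52	3.00	0.03	0.20		true		17.85	0.0029	2.54	0.19	106.35	2.6e-31	15.11	1.1e-17
NBEA	NM_015678.4	c.C2317A	2317	C	A	nonsynonymous_snv	27.3	uncertain	3	3	0.99				segmental_duplication	true	af_patient_mismatch								
NUP214	NM_001318324.2	c.A2263G	2263	A	G	nonsynonymous_snv	23.6	uncertain	3	3	0.52	1.29	0.02	1.01		true		34.26	0.00076	0.51	0.48	85.96	4e-14	1.28	0.46
PDGFRB	NM_001355016.2	c.G1261A	1261	G	A	nonsynonymous_snv	21.2	benign	3	3	0.52	3.54	0.00	0.18		true		Inf	5.3e-05	2.84	0.14	Inf	5.1e-45	20.03	7.7e-26
RABEP1	NM_001291581.2	c.G1755C	1755	G	C	nonsynonymous_snv	22.6	uncertain	3	3	0.52	4.51	0.00	0.36		true		Inf	5.3e-05	1.46	0.56	Inf	8.9e-57	13.22	2.5e-27
ZNF479	NM_001370129.1	c.T1421C	1421	T	C	nonsynonymous_snv	23.3	likely_benign	3	3	0.52	2.58	0.00	0.54		true		Inf	5.3e-05	0.96	1	Inf	1.2e-32	4.89	5.3e-09
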