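database	pathway	absm_z	absm_rank	ganpa_z	ganpa_rank	goganpa_z	goganpa_rank	goganpa_iea_z	goganpa_iea_rank
kegg	renin angiotensin	4.83	1	4.16	10	4.37	4	4.1	6
biocarta	RAC1	4.67	2	4.23	8	4.67	2	4.39	4
reactome	carbohydrates	4.59	3	4.65	1	4.75	1	4.4	3
reactome	glucose transport	4.37	4	3.7	22	4.38	3	4.43	2
biocarta	ECM	4.37	5	3.73	19	4.37	5	3.83	11
reactome	pyruvate	4.29	6	3.6	28	4.29	6	3.49	26
biocarta	CTCF	4.26	7	4.38	4	4.19	8	4.22	5
reactome	basigin	4.19	8	4.31	6	4.19	7	3.31	41
reactome	telomere ends	4.16	9	3.71	20	4.08	14	3.62	14
kegg	glycosaminoglycan	4.13	10	3.67	24	4.13	9	3.92	10
reactome	glycolysis	4.13	11	4.55	2	4.13	10	3.46	29
reactome	bile acids/salts	4.09	12	4.47	3	4.09	13	3.96	8
kegg	pentose phosphate	3.58	30	4.32	5	4.1	12	3.62	15
reactome	gluconeogenesis	3.91	16	4.3	7	3.9	17	3.42	32
kegg	glycolysis gluc.	3.51	35	4.23	9	3.51	34	3.48	27
kegg	ARVC	4.05	13	3.39	38	4.12	11	3.95	9
biocarta	P53 hypoxia	3.6	28	4.08	12	3.6	25	4.67	1
biocarta	VEGF	3.65	26	3.7	21	3.57	28	3.97	7
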