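database	pathway	absm_r1	absm_r2	absm_r3	ganpa_r1	ganpa_r2	ganpa_r3	goganpa_iea_r1	goganpa_iea_r2	goganpa_iea_r3	goganpa_r1	goganpa_r2	goganpa_r3
reactome	syn. di/tri-phosph.	1	23	7	4	12	14	1	27	6	1	24	7
reactome	metablism nts.	4	81	6	6	54	7	3	56	10	4	78	10
kegg	focal adhesion	8	25	54	12	29	59	5	24	37	6	21	48
kegg	pathways in cancer	14	17	37	14	18	30	21	18	24	19	19	40
biocarta	AGR pathway	20	18	1	33	30	1	37	80	1	20	18	1
kegg	melanoma	27	152	101	25	96	77	17	69	35	16	115	80
kegg	acute myeloid leukemia	28	28	57	47	42	62	27	30	18	26	29	60
kegg	pancreatic cancer	30	39	85	34	36	48	36	67	39	34	39	76
reactome	G2/M transition	38	30	90	31	32	58	34	15	108	36	30	89
kegg	prostate cancer	39	12	12	37	19	8	62	19	2	45	5	9
kegg	p53 signaling pathway	40	9	24	30	5	60	33	6	88	39	9	22
kegg	axon guidance	48	8	11	61	9	4	51	8	5	50	10	11
biocarta	PDGF pathway	50	96	114	21	58	81	25	40	47	64	114	125
reactome	cell cycle checkpoints	55	22	80	35	17	106	44	7	128	55	20	86
kegg	renal cell carcinoma	71	55	10	93	55	10	60	72	12	85	56	8
kegg	aldo. reg. Na reabs.	76	163	124	90	77	109	58	78	71	90	171	130
reactome	APC	80	53	22	65	48	18	30	9	57	82	51	20
kegg	reg. actin cyto.	84	87	71	77	61	84	65	90	53	75	71	59
reactome	down strm. sig. trans.	87	102	53	53	60	54	56	51	25	70	88	39
reactome	CDC20	92	113	15	81	111	12	43	47	33	91	111	15
biocarta	longevity pathway	109	154	87	73	112	55	48	76	72	108	149	87
kegg	glioma	111	151	77	74	64	37	83	98	27	104	144	66
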