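metric	concept_id	preferred_label	n_patients	frequency	n_mentions	tfidf	rank_freq	rank_tfidf
freq	C0001	Stéréotypies	36	0.720000	52	0.190677	1	1
freq	C0002	Microcéphalie	28	0.560000	35	0.132965	2	4
freq	C0006	Apraxie	24	0.480000	38	0.153170	3	2
freq	C0004	Épilepsie	23	0.460000	33	0.122051	4	5
freq	C0003	Scoliose	21	0.420000	38	0.143052	5	3
freq	C0005	Retard de croissance	19	0.380000	25	0.094113	6	8
freq	C0008	Troubles du sommeil	18	0.360000	30	0.096906	7	7
freq	C0007	Hypotonie	15	0.300000	23	0.103480	8	6
freq	C0011	Fièvre	13	0.260000	17	0.023752	9	13
freq	C0009	Bruxisme	9	0.180000	12	0.059609	10	9
freq	C0010	Ostéoporose	6	0.120000	10	0.047097	11	10
freq	C0012	Toux	6	0.120000	11	0.019218	12	15
freq	C0013	Vomissements	5	0.100000	11	0.022552	13	14
freq	C0014	Diarrhée	5	0.100000	5	0.011735	14	16
freq	C0017	Eczéma	5	0.100000	10	0.027337	15	11
freq	C0021	Constipation	3	0.060000	8	0.023848	16	12
freq	C0025	Reflux gastrique	2	0.040000	3	0.009443	17	19
freq	C0027	Allergie alimentaire	2	0.040000	3	0.010645	18	17
freq	C0015	Asthme	1	0.020000	1	0.002542	19	27
freq	C0016	Otite	1	0.020000	2	0.005552	20	20
freq	C0018	Anémie	1	0.020000	1	0.002930	21	25
freq	C0019	Rhinite	1	0.020000	1	0.002930	22	26
freq	C0022	Angine	1	0.020000	1	0.003034	23	24
freq	C0023	Migraine	1	0.020000	1	0.003415	24	23
freq	C0024	Obésité	1	0.020000	3	0.009821	25	18
freq	C0029	Dermatite	1	0.020000	1	0.003699	26	22
freq	C0030	Lombalgie	1	0.020000	1	0.004499	27	21
tfidf	C0001	Stéréotypies	36	0.720000	52	0.190677	1	1
tfidf	C0006	Apraxie	24	0.480000	38	0.153170	3	2
tfidf	C0003	Scoliose	21	0.420000	38	0.143052	5	3
tfidf	C0002	Microcéphalie	28	0.560000	35	0.132965	2	4
tfidf	C0004	Épilepsie	23	0.460000	33	0.122051	4	5
tfidf	C0007	Hypotonie	15	0.300000	23	0.103480	8	6
tfidf	C0008	Troubles du sommeil	18	0.360000	30	0.096906	7	7
tfidf	C0005	Retard de croissance	19	0.380000	25	0.094113	6	8
tfidf	C0009	Bruxisme	9	0.180000	12	0.059609	10	9
tfidf	C0010	Ostéoporose	6	0.120000	10	0.047097	11	10
tfidf	C0017	Eczéma	5	0.100000	10	0.027337	15	11
tfidf	C0021	Constipation	3	0.060000	8	0.023848	16	12
tfidf	C0011	Fièvre	13	0.260000	17	0.023752	9	13
tfidf	C0013	Vomissements	5	0.100000	11	0.022552	13	14
tfidf	C0012	Toux	6	0.120000	11	0.019218	12	15
tfidf	C0014	Diarrhée	5	0.100000	5	0.011735	14	16
tfidf	C0027	Allergie alimentaire	2	0.040000	3	0.010645	18	17
tfidf	C0024	Obésité	1	0.020000	3	0.009821	25	18
tfidf	C0025	Reflux gastrique	2	0.040000	3	0.009443	17	19
tfidf	C0016	Otite	1	0.020000	2	0.005552	20	20
tfidf	C0030	Lombalgie	1	0.020000	1	0.004499	27	21
tfidf	C0029	Dermatite	1	0.020000	1	0.003699	26	22
tfidf	C0023	Migraine	1	0.020000	1	0.003415	24	23
tfidf	C0022	Angine	1	0.020000	1	0.003034	23	24
tfidf	C0018	Anémie	1	0.020000	1	0.002930	21	25
tfidf	C0019	Rhinite	1	0.020000	1	0.002930	22	26
tfidf	C0015	Asthme	1	0.020000	1	0.002542	19	27
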