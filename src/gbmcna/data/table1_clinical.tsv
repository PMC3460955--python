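# Clinical characteristics of the 46-patient GBM cohort (age, Karnofsky index,
# tumor localization, extent of surgical removal, relapses, overall survival in
# months after surgery, and the SNP-array platform used per case).
# Surgical removal: ST = subtotal, T = total. The single case marked "alive"
# remained alive at study closure; every other patient had died.
case_id	age_years	gender	karnofsky_pct	tumor_localization	surgical_removal	n_relapses	survival_months	snp_array	vital_status
G6	70	Female	80	Temporal	ST	1	19	500K	deceased
G8	67	Female	90	Deep	ST	0	9	500K	deceased
G10	35	Female	80	Temporal	ST	0	15	500K	deceased
G12	74	Male	70	Temporal	ST	0	1	500K	deceased
G13	39	Female	90	Frontal	ST	1	21	500K	deceased
G14	69	Female	70	Frontal	ST	0	0	500K	deceased
G15	79	Male	80	Parietal	T	0	5	500K	deceased
G17	30	Female	80	Temporal	ST	3	67	500K	deceased
G23	50	Female	80	Frontal	ST	0	14	500K	deceased
G30	71	Female	60	Temporal	ST	0	9	500K	deceased
G34	69	Male	80	Temporal	ST	0	5	500K	deceased
G35	50	Female	50	Frontal	ST	0	2	500K	deceased
G37	70	Male	80	Temporal	T	1	32	500K	deceased
G39	70	Female	70	Frontal	ST	1	18	500K	deceased
G40	45	Female	80	Frontal	ST	1	15	500K	deceased
G42	67	Male	80	Temporal	ST	0	2	500K	deceased
G44	48	Male	80	Frontal	ST	0	22	500K	deceased
G45	76	Female	60	Temporal	ST	0	10	500K	deceased
G46	62	Male	60	Frontal	ST	0	3	500K	deceased
G50	84	Male	70	Temporal	ST	0	11	500K	deceased
G51	60	Male	60	Temporal	ST	0	2	500K	deceased
G52	56	Male	90	Frontal	ST	0	21	500K	deceased
G53	74	Male	60	Frontal	T	0	29	500K	deceased
G55	54	Female	80	Frontal	ST	1	17	500K	deceased
G65	69	Female	60	Parietal	ST	0	1	6.0	deceased
G66	60	Male	80	Occipital	T	0	14	6.0	deceased
G67	68	Female	80	Parietal	ST	0	35	6.0	deceased
G68	72	Male	70	Insular	T	0	26	6.0	deceased
G70	56	Female	80	Occipital	ST	0	21	6.0	deceased
G71	66	Female	60	Parietal	ST	0	10	6.0	deceased
G72	77	Female	70	Temporal	ST	0	1	6.0	deceased
G73	78	Female	60	Parietal	ST	0	4	6.0	deceased
G79	71	Female	60	Occipital	ST	0	6	6.0	deceased
G80	43	Male	80	Frontal	T	1	18	6.0	deceased
G81	62	Female	70	Frontal	ST	0	13	6.0	deceased
G82	78	Male	70	Frontal	ST	0	2	6.0	deceased
G83	75	Male	70	Temporal	ST	0	10	6.0	deceased
G87	45	Male	80	Temporal	ST	1	16	6.0	deceased
G88	71	Male	80	Parietal	ST	0	8	6.0	deceased
G89	51	Male	80	Temporal	ST	0	2	6.0	deceased
G90	57	Female	60	Parietal	ST	0	5	6.0	deceased
G91	73	Female	60	Occipital	ST	0	13	6.0	deceased
G92	54	Female	80	Parietal	T	1	15	6.0	deceased
G93	63	Male	80	Occipital	T	0	29	6.0	alive
G94	79	Female	80	Temporal	ST	0	9	6.0	deceased
G97	53	Male	80	Temporal	T	0	21	6.0	deceased
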