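name	pubchem_cid	ob	dl	tcmsp_id	hit2_id
Poriferasta-7,22E-dien-3beta-Ol	5283663	42.98	0.76	MOL001006
Spinoside A	5281325	41.75	0.4	MOL012537
Β-ecdysterone	27545171	44.23	0.82	MOL012542	C0653
Berberine	2353	36.86	0.78	MOL001454
Coptisine	72322	30.67	0.86	MOL001458
Wogonin	5281703	30.68	0.23	MOL000173
Delta 7-stigmastenol	12315385	37.42	0.75	MOL002643
Baicalein	5281605	33.52	0.21	MOL002714
Baicalin	64982	40.12	0.75	MOL002776
Epiberberine	160876	43.09	0.78	MOL002897
Beta-sitosterol	222284	36.91	0.75	MOL000358	C1178
Inophyllum E	455251	38.81	0.85	MOL003847
Kaempferol	5280863	41.88	0.24	MOL000422
Spinasterol	5281331	42.98	0.76	MOL004355	C0750
Stigmasterol	5280794	43.83	0.76	MOL000449
Palmatine	19009	64.6	0.65	MOL000785
Quercetin	5280343	46.43	0.28	MOL000098
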