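gene_symbol	gene_name	reads_perk_neg	reads_perk_pos	mean_fc	fdr	amp_nsclc	overex_nsclc
Ereg	Epiregulin	5–39	227–376	24.82	2.78e-13	Y	Y
Sox9	SRY-like containing gene 9	6–31	39–330	15.79	7.48e-04	Y	Y
Dlk1	Delta-like 1 homolog	63–400	341–2114	10.46	2.33e-26	Y(SCC)	N
B4galt6	UDP-Gal:betaGlcNAc beta 1,4-galactosyltransferase, 6	7–91	113–491	9.46	1.24e-03	Y(SCC)	Y
Basp1	Brain abundant, membrane attached signal protein 1	0–66	89–307	9.03	1.31e-04	Y > 10%	Y
Itga2	Integrin alpha 2	49–185	185–1239	6.79	2.47e-11	<1%	Y
Cldn4	Claudin 4	7–49	64–117	6.11	1.16e-02	Y	Y
CD24a	CD24a antigen	145–1040	1411–1580	5.94	1.4e-15	No data	Y
Slc38A1	Solute carrier family 38, member 1	60–153	248–716	5.68	1.17e-11	Y	Y
Arntl2	Aryl hydrocarbon receptor nuclear translocator-like 2	15–59	44–156	4.54	4.9e-02	Y > 7%	Y
Dsc2	Desmocollin	14–148	62–302	4.43	4.51e-02	Y(SCC)	Y
Areg	Amphiregulin	156–234	526–831	4.25	4.98e-11	Y	Y
S100a6	S100 calcium binding protein A6	115–215	234–1017	4.00	1.51e-07	Y > 14%	Y
Itgb4	Integrin beta 4	31–89	81–310	3.92	2.29e-02	Y	Y
Atp13a4	ATPase type 13A4	242–399	711–1002	3.92	3.03e-14	Y > 25%	Y
Kif23	Kinesin family member 23	151–359	313–994	3.76	8.81e-07	<1%	Y
Porcn	Porcupine homolog	38–52	76–182	3.59	4.85e-03	<1%	N
Krt8	Keratin 8	67–380	489–699	3.57	1.87e-05	Y	Y
Vcam1	Vascular cell adhesion molecule 1	11–133	75–442	3.57	3.59e-02	<1%	N
Krt18	Keratin 18	503–827	1192–1850	3.50	1.8e-11	Y	Y
Lamc2	Laminin gamma 2	457–677	1104–1825	3.48	2.56e-09	Y > 7%	Y
Tnfrsf12a	Tumour necrosis factor receptor superfamily, 12a	30–54	86–135	3.42	1.47e-02	Y	Y
Tspan8	Tetraspanin 8	329–570	635–1848	3.41	5.23e-06	Y > 5%	Y
Atp6v1g3	ATPase H+ transporting, lysosomal V1 subunit g3	46–94	91–232	3.40	2.8e-03	Y > 7%	N
Ecm1	Extracellular matrix protein 1	44–79	100–173	3.25	7.13e-03	Y > 16%	Y
S100a14	S100 calcium binding protein A14	89–210	218-530	3.18	6.52e-04	Y > 14%	Y
Lgals3bp	Lectin, galactoside-binding, soluble, 3 binding protein	178–333	472–679	3.16	2.09e-05	Y	Y
Nt5e	5’ nucleotidase, ecto	148–339	462–697	3.04	1.2e-05	Y(SCC)	Y
Lad1	Ladinin 1	141–344	401–619	3.01	2.92e-05	Y > 7%	Y
Igfbp5	Insulin-like growth factor binding protein 5	296–422	414–1197	2.99	1.36e-05	<1%	Y
Pdia4	Protein disulphide isomerase associated 4	966–1887	2519–3183	2.98	3.16e-05	Y	Y
CD38	CD38 antigen	37–64	77–167	2.97	3.82e-02	<1%	Y
Krt19	Keratin 19	203–469	664–969	2.96	2.06e-06	<1%	Y
Slc2a1	Solute carrier family 2, member 1	57–114	125–249	2.95	1.11e-02	Y	Y
Myrf	Myelin regulatory factor	57–163	95–474	2.92	1.26e-02	<1%	Y
Plekha6	Pleckstrin homology domain containing, family A, 6	185–353	490–692	2.91	3.34e-05	<1%	Y
Ndrg1	N-MYC downstream regulated gene 1	77–333	208–716	2.84	7.71e-03	Y > 5%	Y
Rabgap1l	RAB GTPase activating protein 1-like	1211–1754	2578–4099	2.83	3.95e-05	Y > 8%	N
Phlda1	Pleckstrin homology-like domain family A, member 1	105–226	175–402	2.82	7.01e-04	<1%	Y
Gapdh	Glyceraldehyde-3-phosphate dehydrogenase	79–106	136–216	2.80	1.08e-02	Y(SCC)	Y
Fabp5	Fatty acid binding protein 5, epidermal	78-175	115–410	2.79	6.15e-03	Y	Y
Cmas	Cytidine monophospho-N-acetylneuraminic acid synthetase	49–106	108–283	2.75	4.21e-02	Y > 5%	Y
Golm1	Golgi membrane protein 1	509–1420	1343–2171	2.75	3.84e-05	N	Y
Ptges	Prostaglandin E synthase	158–286	158–286	2.73	5.26e-03	Y	Y
Stk39	Serine/threonine kinase 39	304–659	872–1127	2.71	2.21e-06	Y	Y
Fam3c	Family with sequence similarity 3, member C	351–642	673–1078	2.65	6.4e-09	Y	N
Pgk1	Phosphoglycerate kinase 1	138–178	220–425	2.61	1.23e-03	<1%	Y
Cacnb3	Calcium channel, voltage dependent, beta 3	56–87	78–147	2.59	3.7e-02	Y	N
Tnfrsf21	Tumour necrosis factor receptor superfamily, 21	121–238	232–348	2.57	1.58e-03	Y	Y
Fmo1	Flavin containing monooxygenase 1	174–256	186–1098	2.57	7.51e-03	Y > 7%	Y
S100a11	S100 calcium binding protein A11	245–696	594–1252	2.53	1.21e-04	Y > 15%	Y
Ceacam1	Carcinoembryonic antigen-related cell adhesion molecule 1	326–608	648–1286	2.50	1.08e-05	Y	Y
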