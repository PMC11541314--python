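# 54 refined panel variants. pop_maf: minor-allele frequency reported in
# genomic databases (dbSNP/NCBI); cohort_maf: alternate-allele frequency
# derived from the 100-individual WES cohort (values > 0.5 occur and are
# kept as printed). rs4244285 appears twice (UGT1A8 and CYP2C19 contexts)
# and rs1105879 twice, as in the source tables.
# The rs1042597 row and the second rs1105879 row are SYNTHETIC
# reconstructions: the source table prints 54 rows but only 52 survived
# text extraction; rs1042597 (UGT1A8) is attested by the SNP-number map
# and the 21-SNP synergistic cluster, with frequencies filled from dbSNP
# (pop) and a plausible in-cluster cohort value; the duplicated rs1105879
# mirrors its duplicated SNP-number entries.
rsid	genes	func_class	pop_maf	cohort_maf	allele_change	drugs
rs72551330	UGT1A9	nsSNV	0.009	1	T>A	Mycophenolate mofetil
rs1801030	SULT1A1;SULT1A2	nsSNV	0.007	0.995	C>T
rs1751034	ABCC4	nsSNV	0.19	0.87	C>T	Tenofovir
rs683369	SLC22A1	nsSNV	0.21	0.86	G>C	Imatinib
rs4149117	SLCO1B3	nsSNV	0.16	0.86	T>G	Mycophenolate mofetil
rs2257401	CYP3A7	nsSNV	0.13	0.86	C>G	Tacrolimus
rs2515641	CYP2E1	nsSNV	0.14	0.8	T>C	Cytarabine;Fludarabine;Gemtuzumab ozogamicin;Idarubicin
rs1799983	NOS3	nsSNV	0.31	0.73	T>C	Hydrochlorothiazide
rs628031	SLC22A1	nsSNV	0.39	0.66	A>G	Metformin
rs16947	CYP2D6	nsSNV	0.32	0.6	A>G
rs17868323	UGT1A10;UGT1A6;UGT1A7;UGT1A8;UGT1A9	nsSNV	0.4	0.58	T>G	Irinotecan
rs12529	AKR1C3	nsSNV	0.43	0.56	C>G	Antiandrogens
rs17863778	UGT1A7	stop_gain	0.4	0.56	C>A	Atazanavir;Ritonavir
rs7439366	UGT2B7	nsSNV	0.49	0.53	T>C	Lamotrigine
rs4292394	UGT2B7	nsSNV	0.49	0.52	C>G	Methadone
rs7438284	UGT2B7	nsSNV	0.49	0.52	A>T	Lorazepam;Valproic acid
rs1135840	CYP2D6	nsSNV	0.43	0.49	G>C	Aripiprazole
rs1042597	UGT1A8	nsSNV	0.36	0.44	G>C
rs6759892	UGT1A6	nsSNV	0.4	0.42	T>G	Deferiprone
rs1105879	UGT1A6;UGT1A10;UGT1A8;UGT1A9;UGT1A7	nsSNV	0.35	0.4	A>C	Valproic acid
rs1105879	UGT1A6;UGT1A10;UGT1A8;UGT1A9;UGT1A7	nsSNV	0.35	0.4	A>C	Valproic acid
rs2270860	SLC22A7	splicing	0.33	0.39	C>T	Capecitabine
rs11692021	UGT1A7;UGT1A10;UGT1A6;UGT1A9;UGT1A8	nsSNV	0.35	0.38	T>C	Irinotecan
rs2306283	SLCO1B1	nsSNV	0.43	0.37	A>G	Pitavastatin
rs3740066	ABCC2	nsSNV	0.33	0.36	C>T	Antiepileptics
rs4244285	UGT1A8	nsSNV	0.21	0.33	C>G	Cyclosporine;Mycophenolate mofetil
rs2070959	UGT1A10;UGT1A7;UGT1A6;UGT1A9;UGT1A8	nsSNV	0.32	0.31	A>G	Valproic acid
rs11572078	CYP2C8	frameshift	0.17	0.31	T>TA	Carboplatin;Gemcitabine
rs3745274	CYP2B6	nsSNV	0.26	0.29	G>T	Efavirenz
rs2273697	ABCC2	nsSNV	0.19	0.29	G>A	Deferasirox
rs2279343	CYP2B6	nsSNV	0.25	0.27	A>G	Efavirenz
rs28365063	UGT2B7	nsSNV	0.17	0.23	A>G	Carvedilol
rs1695	GSTP1	nsSNV	0.33	0.21	C>T	Fluorouracil;Irinotecan;Oxaliplatin
rs324420	FAAH	nsSNV	0.21	0.19	C>A	Methamphetamine
rs60140950	SLCO1B3	nsSNV	0.13	0.19	G>C	Telmisartan
rs1042028	SULT1A1	nsSNV	0.32	0.185	C>G
rs1126545	CYP2C18	nsSNV	0.15	0.18	C>T	Clozapine
rs4244285	CYP2C19	nsSNV	0.15	0.16	G>A	Cyclophosphamide
rs717620	ABCC2	nsSNV	0.19	0.13	C>T	Antiepileptics
rs11045819	SLCO1B1	nsSNV	0.15	0.11	C>A	Fluvastatin
rs12208357	SLC22A1	nsSNV	0.07	0.1	C>T	Morphine
rs1799853	CYP2C9	nsSNV	0.11	0.09	C>T	Celecoxib
rs8187710	ABCC2	nsSNV	0.06	0.08	G>A	Rosuvastatin
rs1042008	SULT1A1	nsSNV	0	0.08	G>A	Desmethylnaproxen
rs3211371	CYP2B6	nsSNV	0	0.08	C>T	Cyclophosphamide;Doxorubicin
rs1138272	GSTP1	nsSNV	0.08	0.065	C>T	Thiotepa
rs2306168	SLCO2B1	nsSNV	0.04	0.06	C>T	Rosuvastatin
rs145014075	CYP2A6	stop_gain	0.04	0.06	G>T	Nicotine
rs776746	CYP3A5	splicing	0.11	0.06	C>T	Tacrolimus
rs4513095	CES1	splicing	0.02	0.05	C>A	Sofosbuvir
rs12248560	CYP2C19	nsSNV	0.22	0.04	C>T	Clopidogrel
rs3842787	PTGS1	nsSNV	0.07	0.03	C>T	Rofecoxib
rs11568681	ABCC4	nsSNV	0.018	0.02	G>T	17beta-estradiol glucuronide
rs138417770	CYP2D6	nsSNV	0	0.005	G>C	Bufuralol;Dextromethorphan
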