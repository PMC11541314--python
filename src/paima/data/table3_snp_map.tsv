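# SNP-number <-> rsID <-> gene map used for the MDR / 3-way interaction
# analyses. Four rsIDs are intentionally duplicated under distinct SNP
# numbers (rs1135840 SNP2/SNP18, rs1105879 SNP13/SNP15, rs7439366
# SNP24/SNP34, rs2306283 SNP32/SNP41), as printed in the source.
snp_no	rsid	gene
SNP1	rs2273697	ABCC2
SNP2	rs1135840	CYP2D6
SNP3	rs16947	CYP2D6
SNP4	rs1138272	GSTP1
SNP5	rs1695	GSTP1
SNP6	rs1042008	SULT1A1
SNP7	rs1042028	SULT1A1
SNP8	rs1801030	SULT1A1
SNP9	rs6759892	UGT1A6
SNP10	rs2070959	UGT1A8
SNP11	rs17868323	UGT1A10
SNP12	rs11692021	UGT1A10
SNP13	rs1105879	UGT1A10
SNP14	rs72551330	UGT1A9
SNP15	rs1105879	UGT1A10
SNP16	rs11568681	ABCC4
SNP17	rs145014075	CYP2A6
SNP18	rs1135840	CYP2D6
SNP19	rs2515641	CYP2E1
SNP20	rs1799853	CYP2C9
SNP21	rs2257401	CYP3A7
SNP22	rs776746	CYP3A5
SNP23	rs28365063	UGT2B7
SNP24	rs7439366	UGT2B7
SNP25	rs7438284	UGT2B7
SNP26	rs3740066	ABCC2
SNP27	rs3745274	CYP2B6
SNP28	rs3211371	CYP2B6
SNP29	rs1126545	CYP2C18
SNP30	rs2270860	SLC22A7
SNP31	rs11045819	SLCO1B1
SNP32	rs2306283	SLCO1B1
SNP33	rs2306168	SLCO2B1
SNP34	rs7439366	UGT2B7
SNP35	rs12529	AKR1C3
SNP36	rs324420	FAAH
SNP37	rs1799983	NOS3
SNP38	rs3842787	PTGS1
SNP39	rs1751034	ABCC4
SNP40	rs11572078	CYP2C8
SNP41	rs2306283	SLCO1B1
SNP42	rs4149117	SLCO1B3
SNP43	rs60140950	SLCO1B3
SNP44	rs4513095	CES1
SNP45	rs17863778	UGT1A7
SNP46	rs138417770	CYP2D6
SNP47	rs717620	ABCC2
SNP48	rs8187710	ABCC2
SNP49	rs2279343	CYP2B6
SNP50	rs12208357	SLC22A1
SNP51	rs628031	SLC22A1
SNP52	rs683369	SLC22A1
SNP53	rs1042597	UGT1A8
SNP54	rs4244285	CYP2C19
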