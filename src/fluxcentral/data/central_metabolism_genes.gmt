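M_GLC_IN	Glucose uptake	SLC2A1	SLC2A2	SLC2A3	SLC2A4	SLC2A5
M_HK	Glucose phosphorylation	HK1	HK2	HK3	GCK	HKDC1
M_G6P_G3P	Upper glycolysis G6P to G3P	GPI	PFKL	PFKM	PFKP	ALDOA	ALDOB	ALDOC	TPI1
M_G3P_3PG	Glycolysis G3P to 3PG	GAPDH	PGK1	PGK2
M_3PG_PEP	Glycolysis 3PG to PEP	PGAM1	PGAM2	ENO1	ENO2	ENO3
M_PEP_PYR	Pyruvate kinase	PKM	PKLR
M_PYR_LAC	Lactate production	LDHA	LDHB	LDHC
M_LAC_OUT	Lactate export	SLC16A1	SLC16A3	SLC16A8
M_PYR_TRANS	Mitochondrial pyruvate carrier	MPC1	MPC2
M_PDH	Pyruvate dehydrogenase	PDHA1	PDHB	DLAT	DLD	PDHX
M_CS	Citrate synthase	CS
M_CIT_ACO	Citrate to cis-aconitate	ACO2
M_ACO_ICIT	cis-Aconitate to isocitrate	ACO2	ACO1
M_ICIT_AKG	Isocitrate dehydrogenase	IDH2	IDH3A	IDH3B	IDH3G
M_AKG_SUCCOA	2OG dehydrogenase	OGDH	OGDHL	DLST	DLD
M_SUCCOA_SUC	Succinyl-CoA synthetase	SUCLG1	SUCLG2	SUCLA2
M_SUC_FUM	Succinate dehydrogenase	SDHA	SDHB	SDHC	SDHD
M_FUM_MAL	Fumarase	FH
M_MAL_OAA	Malate dehydrogenase	MDH2
M_GLN_IN	Glutamine import	SLC1A5	SLC38A1	SLC38A2	SLC7A5
M_GLU_IN	Glutamate import	SLC1A1	SLC1A2	SLC1A3
M_GLN_GLU_C	Cytosolic glutaminase	GLS	GLS2
M_GLN_TRANS	Mitochondrial glutamine transport	SLC38A1	SLC1A5
M_GLS_M	Mitochondrial glutaminase	GLS	GLS2
M_GLUD	Glutamate dehydrogenase	GLUD1	GLUD2	GOT2
M_GABA_SHUNT	GABA shunt glutamate to succinate	GAD1	GAD2	ABAT	ALDH5A1
M_GLU_TRANS	Mitochondrial glutamate carrier	SLC25A22	SLC25A18
M_GLN_AA	Glutamine to other amino acids	ASNS	PPAT	GFPT1	CTPS1
M_GLU_PRO	Proline biosynthesis	ALDH18A1	PYCR1	PYCR2	PYCR3
M_ASP_ASN	Asparagine biosynthesis	ASNS
M_GSH_SYN_C	Cytosolic glutathione biosynthesis	GCLC	GCLM	GSS
M_GSH_TRANS	Mitochondrial glutathione transport	SLC25A39	SLC25A40
M_GSH_SYN_M	Mitochondrial glutathione biosynthesis	GCLC	GCLM	GSS
M_GPX	Glutathione peroxidase GSH to GSSG	GPX1	GPX2	GPX3	GPX4
M_GSR	Glutathione reductase GSSG to GSH	GSR
M_GSH_AA	Glutathione to other amino acids	GGT1	GGT5	GGCT	CHAC1	OPLAH
M_G3P_NUC	Nucleotide biosynthesis from G3P	PRPS1	PRPS2	PPAT	GART	ATIC
M_3PG_SER	Serine biosynthesis from 3PG	PHGDH	PSAT1	PSPH
M_OAA_ASP	Aspartate-malate shuttle	GOT1	GOT2	MDH1	SLC25A12	SLC25A13
M_CIT_FA	Citrate to fatty acid biosynthesis	SLC25A1	ACLY	ACACA	FASN
M_AKG_TRANS	2OG mitochondria to cytosol transport	SLC25A11
M_AKG_2HG	2OG to 2HG	IDH1	IDH2
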