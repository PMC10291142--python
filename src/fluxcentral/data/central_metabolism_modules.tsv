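module_id	role	metabolite_id	compartment	met_role
M_GLC_IN	input	glc_e	extracellular	end
M_GLC_IN	output	glc_c	cytosol	intermediate
M_HK	input	glc_c	cytosol	intermediate
M_HK	output	g6p_c	cytosol	intermediate
M_G6P_G3P	input	g6p_c	cytosol	intermediate
M_G6P_G3P	output	g3p_c	cytosol	intermediate
M_G3P_3PG	input	g3p_c	cytosol	intermediate
M_G3P_3PG	output	pg3_c	cytosol	intermediate
M_3PG_PEP	input	pg3_c	cytosol	intermediate
M_3PG_PEP	output	pep_c	cytosol	intermediate
M_PEP_PYR	input	pep_c	cytosol	intermediate
M_PEP_PYR	output	pyr_c	cytosol	intermediate
M_PYR_LAC	input	pyr_c	cytosol	intermediate
M_PYR_LAC	output	lac_c	cytosol	intermediate
M_LAC_OUT	input	lac_c	cytosol	intermediate
M_LAC_OUT	output	lac_e	extracellular	end
M_PYR_TRANS	input	pyr_c	cytosol	intermediate
M_PYR_TRANS	output	pyr_m	mitochondria	intermediate
M_PDH	input	pyr_m	mitochondria	intermediate
M_PDH	output	accoa_m	mitochondria	intermediate
M_PDH	output	co2_m	mitochondria	end
M_CS	input	accoa_m	mitochondria	intermediate
M_CS	input	oaa_m	mitochondria	intermediate
M_CS	output	cit_m	mitochondria	intermediate
M_CIT_ACO	input	cit_m	mitochondria	intermediate
M_CIT_ACO	output	aco_m	mitochondria	intermediate
M_ACO_ICIT	input	aco_m	mitochondria	intermediate
M_ACO_ICIT	output	icit_m	mitochondria	intermediate
M_ICIT_AKG	input	icit_m	mitochondria	intermediate
M_ICIT_AKG	output	akg_m	mitochondria	intermediate
M_ICIT_AKG	output	co2_m	mitochondria	end
M_AKG_SUCCOA	input	akg_m	mitochondria	intermediate
M_AKG_SUCCOA	output	succoa_m	mitochondria	intermediate
M_AKG_SUCCOA	output	co2_m	mitochondria	end
M_SUCCOA_SUC	input	succoa_m	mitochondria	intermediate
M_SUCCOA_SUC	output	suc_m	mitochondria	intermediate
M_SUC_FUM	input	suc_m	mitochondria	intermediate
M_SUC_FUM	output	fum_m	mitochondria	intermediate
M_FUM_MAL	input	fum_m	mitochondria	intermediate
M_FUM_MAL	output	mal_m	mitochondria	intermediate
M_MAL_OAA	input	mal_m	mitochondria	intermediate
M_MAL_OAA	output	oaa_m	mitochondria	intermediate
M_GLN_IN	input	gln_e	extracellular	end
M_GLN_IN	output	gln_c	cytosol	intermediate
M_GLU_IN	input	glu_e	extracellular	end
M_GLU_IN	output	glu_c	cytosol	intermediate
M_GLN_GLU_C	input	gln_c	cytosol	intermediate
M_GLN_GLU_C	output	glu_c	cytosol	intermediate
M_GLN_TRANS	input	gln_c	cytosol	intermediate
M_GLN_TRANS	output	gln_m	mitochondria	intermediate
M_GLS_M	input	gln_m	mitochondria	intermediate
M_GLS_M	output	glu_m	mitochondria	intermediate
M_GLS_M	output	nh3_m	mitochondria	end
M_GLUD	input	glu_m	mitochondria	intermediate
M_GLUD	output	akg_m	mitochondria	intermediate
M_GLUD	output	nh3_m	mitochondria	end
M_GABA_SHUNT	input	glu_m	mitochondria	intermediate
M_GABA_SHUNT	output	suc_m	mitochondria	intermediate
M_GLU_TRANS	input	glu_c	cytosol	intermediate
M_GLU_TRANS	output	glu_m	mitochondria	intermediate
M_GLN_AA	input	gln_c	cytosol	intermediate
M_GLN_AA	output	aa_c	cytosol	end
M_GLU_PRO	input	glu_c	cytosol	intermediate
M_GLU_PRO	output	pro_c	cytosol	end
M_ASP_ASN	input	asp_c	cytosol	intermediate
M_ASP_ASN	output	asn_c	cytosol	end
M_GSH_SYN_C	input	glu_c	cytosol	intermediate
M_GSH_SYN_C	input	cys_c	cytosol	end
M_GSH_SYN_C	input	gly_c	cytosol	end
M_GSH_SYN_C	output	gsh_c	cytosol	intermediate
M_GSH_TRANS	input	gsh_c	cytosol	intermediate
M_GSH_TRANS	output	gsh_m	mitochondria	intermediate
M_GSH_SYN_M	input	glu_m	mitochondria	intermediate
M_GSH_SYN_M	output	gsh_m	mitochondria	intermediate
M_GPX	input	gsh_m	mitochondria	intermediate
M_GPX	output	gssg_m	mitochondria	intermediate
M_GSR	input	gssg_m	mitochondria	intermediate
M_GSR	output	gsh_c	cytosol	intermediate
M_GSH_AA	input	gsh_c	cytosol	intermediate
M_GSH_AA	output	aa_c	cytosol	end
M_G3P_NUC	input	g3p_c	cytosol	intermediate
M_G3P_NUC	output	nuc_c	cytosol	end
M_3PG_SER	input	pg3_c	cytosol	intermediate
M_3PG_SER	output	ser_c	cytosol	end
M_OAA_ASP	input	oaa_m	mitochondria	intermediate
M_OAA_ASP	output	asp_c	cytosol	intermediate
M_CIT_FA	input	cit_m	mitochondria	intermediate
M_CIT_FA	output	fa_c	cytosol	end
M_AKG_TRANS	input	akg_m	mitochondria	intermediate
M_AKG_TRANS	output	akg_c	cytosol	intermediate
M_AKG_2HG	input	akg_c	cytosol	intermediate
M_AKG_2HG	output	hg2_c	cytosol	end
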