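# Resting-state network sphere ROIs (MNI mm, radius 6 mm).
# Mixed-sign shorthand in the source table is expanded into explicit
# left/right rows; names are prefixed with the network.
name	network	kind	x	y	z	radius_mm	label_id
SAL_dACC_L	SAL	sphere	-5	14	42	6
SAL_dACC_R	SAL	sphere	5	14	42	6
SAL_aPFC_R	SAL	sphere	32	45	30	6
SAL_aPFC_L	SAL	sphere	-35	45	30	6
SAL_aINS_L	SAL	sphere	-32	16	6	6
SAL_aINS_R	SAL	sphere	32	16	6	6
SAL_LPC_L	SAL	sphere	-62	-45	30	6
SAL_LPC_R	SAL	sphere	62	-45	30	6
REW_dACC_L	REW	sphere	-5	14	42	6
REW_dACC_R	REW	sphere	5	14	42	6
REW_aINS_L	REW	sphere	-32	16	6	6
REW_aINS_R	REW	sphere	32	16	6	6
REW_AMYG_L	REW	sphere	21.4	-0.3	-18.8	6
REW_AMYG_R	REW	sphere	-25.1	-0.2	-18.5	6
REW_HYPO_R	REW	sphere	5	-1	-13	6
REW_HYPO_L	REW	sphere	-4	-1	-13	6
REW_NAcc_L	REW	sphere	-8.8	13.2	-7.8	6
REW_NAcc_R	REW	sphere	11.6	13.3	-7.7	6
REW_Caudate_L	REW	sphere	-10	13	9.5	6
REW_Caudate_R	REW	sphere	11	13	9.5	6
REW_Putamen_L	REW	sphere	-23	-2	3	6
REW_Putamen_R	REW	sphere	23	-2	3	6
REW_vStr_L	REW	sphere	-14.6	11.4	-5.4	6
REW_vStr_R	REW	sphere	21.9	15.3	-1.3	6
DA_FEF_L	DA	sphere	-29	-9	54	6
DA_FEF_R	DA	sphere	29	-9	54	6
DA_IPS_L	DA	sphere	-26	-66	48	6
DA_IPS_R	DA	sphere	26	-66	48	6
DA_aIPS_R	DA	sphere	41	-39	45	6
DA_aIPS_L	DA	sphere	-44	-39	45	6
DA_MTG_L	DA	sphere	-50	-66	-6	6
DA_MTG_R	DA	sphere	53	-63	-6	6
CE_dmPFC	CE	sphere	0	24	46	6
CE_aPFC_L	CE	sphere	-44	45	0	6
CE_aPFC_R	CE	sphere	44	45	0	6
CE_SPG_L	CE	sphere	-50	-51	45	6
CE_SPG_R	CE	sphere	50	-51	45	6
VIS_V1_L	VIS	sphere	-11	-81	7	6
VIS_V1_R	VIS	sphere	11	-78	9	6
VIS_V2_R	VIS	sphere	29	-92	2	6
VIS_V2_L	VIS	sphere	-19	-92	2	6
VIS_V3_L	VIS	sphere	-45	-75	11	6
VIS_V3_R	VIS	sphere	44	-75	5	6
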