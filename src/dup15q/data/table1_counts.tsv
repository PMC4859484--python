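# Carrier counts for interstitial 15q11.2-q13.3 duplications by study, cohort class
# and parental origin.  One row per (study, cohort class).  n_total is the number of
# subjects screened; NA where a study reported carriers but not the cohort size
# (such rows contribute to the maternal:paternal origin ratio only).
study_id	cohort_class	carriers_maternal	carriers_paternal	carriers_unknown	n_total	usable_for_prevalence	notes
costain_canada	SZ	3	0	0	459	true	Affymetrix
priebe_germany	SZ	1	1	0	1637	true	Illumina
vacic_us_ireland	SZ	0	0	0	802	true	NimbleGen
szatkiewicz_sweden	SZ	0	0	0	4097	true	ISC overlap of 622 subjects removed
ingason_sgene_isc	SZ	4	0	0	6898	true	SGENE+ISC European cohorts
iceland_new	SZ	1	0	0	698	true	new data
germany_new	SZ	4	0	0	400	true	new data
rees_clozuk	SZ	8	0	0	6882	true	UK CLOZAPINE-treated
ikeda_japan	SZ	0	0	0	575	true	Affymetrix
japan_new	SZ	1	0	0	1745	true	new data
levinson_mgs	SZ	2	0	0	3945	true	USA MGS
iceland_asd	DD_ASD_MCA	2	0	0	491	true	ASD; new data
pinto_agp_ssc_agre	DD_ASD_MCA	10	2	1	5106	true	AGP SSC AGRE
ahn_bbgre	DD_ASD_MCA	7	2	11	20260	true	UK BBGRE referrals
dittwald_baylor	DD_ASD_MCA	0	0	18	25144	true	clinical genetics referrals; origin untyped
urraca_dup15q	DD_ASD_MCA	10	4	0	NA	false	cohort size not reported; origin ratio only
al_ageeli_france	DD_ASD_MCA	10	1	0	NA	false	cohort size not reported; origin ratio only
aypar_mayo	DD_ASD_MCA	11	1	0	NA	false	cohort size not reported; origin ratio only
costain_canada	CONTROL	0	0	0	416	true
priebe_germany	CONTROL	0	0	0	1627	true
vacic_us_ireland	CONTROL	0	0	0	742	true
szatkiewicz_sweden	CONTROL	0	0	0	5480	true
ingason_sgene_isc	CONTROL	0	0	0	9848	true	excludes Icelanders counted below
iceland_population	CONTROL	4	4	0	115000	true	population-based; carrier relatives retained
germany_new	CONTROL	0	0	0	400	true
rees_clozuk	CONTROL	0	0	0	11255	true
ikeda_japan	CONTROL	0	0	0	564	true
japan_new	CONTROL	0	0	0	837	true
levinson_mgs	CONTROL	0	0	0	3611	true
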