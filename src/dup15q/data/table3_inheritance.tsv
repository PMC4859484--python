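# De novo vs inherited interstitial 15q11.2-q13.3 duplications by parental origin,
# among carriers with both parents tested.
study_id	origin	de_novo	inherited
urraca_dup15q	MATERNAL	9	1
urraca_dup15q	PATERNAL	2	2
al_ageeli_france	MATERNAL	6	3
al_ageeli_france	PATERNAL	0	1
pinto_agp_ssc_agre	MATERNAL	5	5
pinto_agp_ssc_agre	PATERNAL	2	0
aypar_mayo	MATERNAL	3	3
aypar_mayo	PATERNAL	0	0
current_study	MATERNAL	6	12
current_study	PATERNAL	3	2
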