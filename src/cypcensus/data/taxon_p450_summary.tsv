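taxon	n_species_analyzed	n_species_with_p450s	n_genera_analyzed	n_genera_with_p450s	n_p450s	n_families	n_subfamilies	n_p450s_in_bgcs	dominant_family
Alphaproteobacteria	599	241	164	82	874	143	214	21	CYP202
Firmicutes	972	229			712	14	53	126	CYP107
Streptomyces	203	203			5460	253	698	1231	CYP107
Mycobacteria	60	60			1784	77	132	204	CYP125
Cyanobacteria	114	114			341	36	79	27	CYP110
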