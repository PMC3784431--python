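# Published counts of candidate habitat-marker CAZy families across 15
# Flavobacterium strains (terrestrial vs aquatic clade), used as a small
# real-data fixture for clade-unique family detection.
genome_id	clade	GH28	GH78	GH106	GH10	GH115	CE2	CBM6	GH27	GH43	GH51	GH1	GH130	GH95	PL1	GH18	GH89
F_johnsoniae_UW101	terrestrial	7	3	2	3	1	1	4	2	10	2	1	5	2	7	4	1
F_sp_F52	terrestrial	6	3	2	1	1	1	6	2	13	2	2	5	2	6	3	1
F_sp_CF136	terrestrial	10	4	2	3	1	1	3	4	25	6	1	4	5	11	3	1
F_sp_URHB0058	terrestrial	11	3	2	1	3	1	3	1	10	3	1	4	2	5	3	1
F_rivuli_DSM21788	terrestrial	4	1	2	0	0	1	1	2	13	3	2	2	3	1	0	0
F_sp_B17	terrestrial	0	0	0	1	2	0	4	1	8	1	0	1	1	0	1	1
F_soli_DSM19725	terrestrial	1	0	0	0	3	1	2	1	7	0	1	2	0	1	0	0
F_sp_WG21	terrestrial	3	0	0	0	0	0	1	0	1	0	1	0	0	2	3	0
F_antarcticum_DSM19726	aquatic	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
F_branchiophilum_FL15	aquatic	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
F_columnare_ATCC49512	aquatic	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
F_indicum_GPTSA100-9	aquatic	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
F_psychrophilum_JIP0286	aquatic	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
F_frigoris_PS1	aquatic	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
F_sp_ACAM123	aquatic	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0
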