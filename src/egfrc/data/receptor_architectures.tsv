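species	label	tm_count	signal_peptide	cys_rich_count	tk_active	assumed
M_leidyi	egfr1	1	yes	3	yes
A_queenslandica	egfr1	1	yes	1	yes	sp
X_bocki	egfr1	1	yes	2	yes
X_bocki	egfr2	1	yes	3	yes
M_stichopi	egfr1	1	yes	2	yes
M_stichopi	egfr2	1	yes	3	yes
M_stichopi	egfr3	1	yes	4	yes
I_pulchra	egfr1	1	yes	1	yes
I_pulchra	egfr2	1	yes	1	yes
I_pulchra	egfr3	1	yes	3	yes
I_pulchra	egfr4	1	yes	3	yes	sp
I_pulchra	egfr5	1	yes	3	yes	tm,sp,cys
C_macropyga	egfr1	1	yes	4	yes
C_macropyga	egfr2	1	yes	4	yes
C_macropyga	egfr3	1	yes	1	yes
P_caudatus	egfr1	1	yes	3	yes	sp
H_spinulosus	egfr1	1	yes	3	yes
C_elegans	egfr1	1	yes	3	yes
T_castaneum	egfr1	1	yes	2	yes
D_melanogaster	egfr1	1	yes	3	yes
M_lignano	egfr1	1	yes	1	yes
M_lignano	egfr2	1	yes	2	yes
M_lignano	egfr3	1	yes	2	yes
M_lignano	egfr4	1	yes	3	yes
M_lignano	egfr5	1	yes	4	yes
M_lignano	egfr6	1	yes	3	yes	sp,cys
M_lignano	egfr7	1	yes	3	yes	tm,sp,cys
M_lignano	egfr8	1	yes	3	yes	tm,sp,cys
P_vittatus	egfr1	1	yes	2	yes
P_vittatus	egfr2	1	yes	2	yes
P_vittatus	egfr3	1	yes	3	yes
P_vittatus	egfr4	1	yes	3	yes
P_vittatus	egfr5	1	yes	3	yes
P_vittatus	egfr6	1	yes	3	yes	sp
S_mediterranea	egfr1	1	yes	3	yes
S_mediterranea	egfr2	1	yes	3	yes
S_mediterranea	egfr3	1	yes	3	yes
S_mediterranea	egfr4	1	yes	3	yes
S_mediterranea	egfr5	1	yes	4	yes	sp
S_mediterranea	egfr6	1	yes	4	no
S_mansoni	egfr1	1	yes	3	yes
S_mansoni	egfr2	1	yes	5	yes	sp
S_mansoni	egfr3	1	yes	5	yes	sp
E_multilocularis	egfr1	1	yes	3	yes
E_multilocularis	egfr2	1	yes	3	yes	sp
E_multilocularis	egfr3	1	yes	4	yes	sp
L_gigantea	egfr1	1	yes	2	yes
L_gigantea	egfr2	1	yes	3	no	tm,sp
C_gigas	egfr1	1	yes	3	yes	sp,cys
C_gigas	egfr2	1	yes	3	yes	tm,sp,cys
O_fusiformis	egfr1	1	yes	3	yes
C_teleta	egfr1	1	yes	3	yes	sp
H_robusta	egfr1	1	yes	2	yes	sp
H_robusta	egfr2	1	yes	3	yes	sp
H_robusta	egfr3	1	yes	4	yes	sp
H_robusta	egfr4	1	yes	4	yes	sp
H_robusta	egfr5	1	yes	3	yes	tm,sp,cys
H_robusta	egfr6	1	yes	3	yes	tm,sp,cys
L_ruber	egfr1	1	yes	3	yes
M_membranacea	egfr1	1	yes	3	yes
M_membranacea	egfr2	1	yes	3	yes
M_membranacea	egfr3	2	yes	3	yes	sp
T_transversa	egfr1	1	yes	3	yes
N_anomala	egfr1	1	yes	3	yes
P_harmeri	egfr1	1	yes	3	yes	tm,sp,cys
S_kowalevskii	egfr1	1	yes	4	yes	sp
S_purpuratus	egfr1	1	yes	4	yes	sp
B_floridae	egfr1	1	yes	3	yes	tm,sp,cys
C_intestinalis	egfr1	1	yes	1	yes
C_intestinalis	egfr2	1	yes	3	yes	sp
H_sapiens	egfr1	1	yes	2	yes
H_sapiens	egfr2	1	yes	2	yes
H_sapiens	egfr3	1	yes	2	no
H_sapiens	egfr4	1	yes	2	yes
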