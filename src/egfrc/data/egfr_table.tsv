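species	clade	egfr_count	inactive_tk_count
M_leidyi	Ctenophora	1	0
A_queenslandica	Porifera	1	0
T_adhaerens	Placozoa	0	0
N_vectensis	Cnidaria	0	0
H_magnipapillata	Cnidaria	0	0
X_bocki	Xenacoelomorpha	2	0
M_stichopi	Xenacoelomorpha	3	0
I_pulchra	Xenacoelomorpha	5	0
C_macropyga	Xenacoelomorpha	3	0
P_caudatus	Priapulida	1	0
H_spinulosus	Priapulida	1	0
C_elegans	Nematoda	1	0
T_castaneum	Arthropoda	1	0
D_melanogaster	Arthropoda	1	0
L_squamata	Gastrotricha	0	0
M_lignano	Platyhelminthes	8	0
P_vittatus	Platyhelminthes	6	0
S_mediterranea	Platyhelminthes	6	1
S_mansoni	Platyhelminthes	3	0
E_multilocularis	Platyhelminthes	3	0
L_gigantea	Mollusca	2	1
C_gigas	Mollusca	2	0
O_fusiformis	Annelida	1	0
C_teleta	Annelida	1	0
H_robusta	Annelida	6	0
L_ruber	Nemertea	1	0
M_membranacea	Bryozoa	3	0
T_transversa	Brachiopoda	1	0
N_anomala	Brachiopoda	1	0
P_harmeri	Phoronida	1	0
S_kowalevskii	Hemichordata	1	0
S_purpuratus	Echinodermata	1	0
B_floridae	Chordata	1	0
C_intestinalis	Chordata	2	0
H_sapiens	Chordata	4	1
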