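species	clade	ligand_count	egf_like_count	nrg_like_count
M_leidyi	Ctenophora	1	1	0
A_queenslandica	Porifera	1	1	0
T_adhaerens	Placozoa	1	1	0
N_vectensis	Cnidaria	0	0	0
H_magnipapillata	Cnidaria	0	0	0
X_bocki	Xenacoelomorpha	2	1	1
M_stichopi	Xenacoelomorpha	5	4	1
I_pulchra	Xenacoelomorpha	5	2	3
C_macropyga	Xenacoelomorpha	2	0	2
P_caudatus	Priapulida	1	1	0
H_spinulosus	Priapulida	2	1	1
C_elegans	Nematoda	1	1	0
T_castaneum	Arthropoda	1	1	0
D_melanogaster	Arthropoda	4	3	1
L_squamata	Gastrotricha	2	2	0
M_lignano	Platyhelminthes	2	1	1
P_vittatus	Platyhelminthes	9	7	2
S_mediterranea	Platyhelminthes	9	8	1
S_mansoni	Platyhelminthes	1	0	1
E_multilocularis	Platyhelminthes	2	1	1
L_gigantea	Mollusca	1	1	0
C_gigas	Mollusca	1	0	1
O_fusiformis	Annelida	3	2	1
C_teleta	Annelida	4	4	0
H_robusta	Annelida	4	3	1
L_ruber	Nemertea	4	3	1
M_membranacea	Bryozoa	2	1	1
T_transversa	Brachiopoda	1	1	0
N_anomala	Brachiopoda	1	1	0
S_kowalevskii	Hemichordata	2	1	1
S_purpuratus	Echinodermata	1	0	1
B_floridae	Chordata	5	4	1
C_intestinalis	Chordata	2	2	0
H_sapiens	Chordata	11	7	4
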