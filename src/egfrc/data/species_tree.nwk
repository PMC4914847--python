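(M_leidyi,(A_queenslandica,(T_adhaerens,((N_vectensis,H_magnipapillata)Cnidaria,((X_bocki,M_stichopi,I_pulchra,C_macropyga)Xenacoelomorpha,((((P_caudatus,H_spinulosus)Priapulida,C_elegans,(T_castaneum,D_melanogaster)Arthropoda)Ecdysozoa,((L_squamata,(M_lignano,P_vittatus,S_mediterranea,S_mansoni,E_multilocularis)Platyhelminthes)Rouphozoa,(L_gigantea,C_gigas)Mollusca,(O_fusiformis,C_teleta,H_robusta)Annelida,L_ruber,M_membranacea,(T_transversa,N_anomala)Brachiopoda,P_harmeri)Spiralia)Protostomia,((S_kowalevskii,S_purpuratus)Ambulacraria,(B_floridae,C_intestinalis,H_sapiens)Chordata)Deuterostomia)Nephrozoa)Bilateria)Planulozoa)ParaHoxozoa)Benthozoa)Metazoa;
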