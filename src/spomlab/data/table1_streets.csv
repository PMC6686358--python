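street,abbrev,n_tree_bases,smallest_distance_m,nearest_green_space,pct_LM,pct_LMR,pct_PRM
Rue Baron le Roy,BARO,62,166,Railways of Lyon and Bercy stations,53,13,33
Place du Bataillon du Pacifique,BATA,31,63,Railways of the Lyon and Bercy stations,40,0,60
Boulevard de Bercy (1),BERC,126,33,Railways of the Lyon and Bercy stations,47,27,27
Boulevard de Bercy (2),BERY,99,148,Seine River,40,13,47
Rue de Charenton,CHAR,144,41,Railways of Lyon and Bercy stations,53,13,33
Rue Daumesnil,DAUM,186,7,Rene Dumont footpath,27,7,67
Rue Joseph Kessel,KESS,69,3,Bercy Park,33,13,53
Place Lachambeaudie,LACH,31,13,Railways of Lyon and Bercy stations,27,0,73
Rue Montgallet,MONT,52,125,Rene Dumont footpath,40,13,47
Rue Pommard,POMM,39,17,Bercy Park,27,0,73
Quai de la Rapee,RAPE,97,64,Seine River,47,13,40
Rue de Bercy,RBER,136,88,Railways of the Lyon and Bercy stations,40,7,53
Rue de Reuilly,REUI,145,224,Rene Dumont footpath,60,7,33
Rue Taine,TAIN,62,38,Railways of the Lyon and Bercy stations,20,7,73
Rue des Terroirs de France,TERR,45,177,Seine River,47,7,47
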