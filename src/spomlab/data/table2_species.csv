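species,seed_weight_mg,dispersal_system,longevity_class,life_span,max_height_cm,pct_LM,pct_LMR,pct_PRM
Capsella bursa-pastoris,2.5,0,2,annual,50,53,13,33
Chenopodium album,71.4,0,2,annual,100,53,0,47
Conyza canadensis,15,0,1,annual,80,47,7,47
Hordeum murinum,366.4,1,1,annual,50,40,20,40
Lactuca serriola,45,1,1,annual,100,40,7,53
Lolium perenne,228,0,1,perennial,60,47,13,40
Plantago major,250,1,2,perennial,50,20,0,80
Poa annua,30,0,2,annual,30,33,13,53
Polygonum aviculare,92.1,0,2,annual,80,33,7,60
Senecio inaequidens,30,0,2,perennial,80,33,7,60
Senecio vulgaris,20,1,1,annual,60,53,0,47
Sisymbrium irio,7.3,0,1,annual,90,47,13,40
Sonchus oleraceus,24.7,1,2,annual,80,27,0,73
Stellaria media,35,0,1,perennial,30,33,33,33
Taraxacum campylodes,50,1,2,perennial,40,33,13,53
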