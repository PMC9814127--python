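species,region,in_situ,ex_situ,note
Brassica montana,Lazio,4,0,
Brassica montana,Liguria,58,3,
Brassica montana,Marche,15,0,
Brassica montana,Tuscany,21,4,
Brassica montana,San Marino,2,0,footnote: recorded outside the Italian administrative regions
Brassica insularis,Campania,2,0,
Brassica insularis,Sardinia,84,1,
Brassica insularis,Sicily,6,0,
Brassica villosa,Sicily,74,14,
Brassica rupestris,Calabria,1,0,
Brassica rupestris,Lazio,4,0,
Brassica rupestris,Marche,3,0,
Brassica rupestris,Sicily,53,9,
Brassica macrocarpa,Sicily,11,0,
Brassica glabrescens,Friuli-Venezia Giulia,9,0,
Brassica procumbens,Tuscany,7,0,
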