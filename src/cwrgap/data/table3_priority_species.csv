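species,genus,endemism,red_list,populations,within_n,within_pct_printed
Allium agrigentinum,Allium,Sicily,EN,3,0,0
Allium franciniae,Allium,Sicily,NT,2,1,50
Allium hemisphaericum,Allium,Sicily,VU,12,10,83
Allium lehmannii,Allium,Sicily,NT,15,10,67
Allium lopadusanum,Allium,Sicily,EN,1,0,0
Allium nebrodense,Allium,Sicily,VU,4,4,100
Allium obtusiflorum,Allium,Subendemic,NT,13,6,46
Allium pentadactyli,Allium,Italy,NT,2,1,50
Allium permixtum,Allium,,VU,6,5,83
Allium trifoliatum,Allium,,NT,1,0,0
Allium vernale,Allium,,VU,2,1,50
Brassica glabrescens,Brassica,Italy,NT,9,3,33
Brassica insularis,Brassica,Subendemic,,44,33,75
Brassica macrocarpa,Brassica,Sicily,CR,6,6,100
Brassica montana,Brassica,,,21,18,86
Brassica procumbens,Brassica,,,3,1,33
Brassica rupestris,Brassica,Sicily,,23,13,57
Brassica villosa,Brassica,Sicily,NT,35,9,26
Triticum uniaristatum,Triticum,,,7,4,57
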