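genus,n_species,populations,within_n,within_pct_printed
Allium,43,1687,1144,68
Beta,1,15,,53
Brassica,11,215,146,68
Secale,1,33,,82
Triticum,4,46,,40
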