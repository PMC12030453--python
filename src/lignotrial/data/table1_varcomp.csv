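factor,lignin_pct,hemicellulose_pct,cellulose_pct,lignin_yield,hemicellulose_yield,cellulose_yield,ethanol_yield
environment,0.00,0.00,1.75,1725314,2089594,5163086,5099719
genotype,1.69,0.46,15.52,7989112,3879290,545155,1625688
gxe,0.00,0.11,0.94,0,0,0,0
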