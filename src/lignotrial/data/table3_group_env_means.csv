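group,environment,lignin_pct,hemicellulose_pct,cellulose_pct,lignin_yield,hemicellulose_yield,cellulose_yield,ethanol_yield
mariola,IRRI,15.84,17.55,33.99,5176.6,5636,9960,9254
mariola,DRY,16.28,15.22,29.27,1607.1,1384,3177,2757
guayule_hybrid,IRRI,15.06,16.75,25.87,6876.9,7592,11415,11318
guayule_hybrid,DRY,14.43,13.47,19.14,1928.7,1717,2615,2854
guayule,IRRI,16.34,16.34,22.22,4351.6,4461,6412,6833
guayule,DRY,16.70,14.46,18.73,1390.5,1020,1608,1823
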