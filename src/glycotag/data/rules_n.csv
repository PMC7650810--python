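code,glycan_class,core,antennae_min,antennae_max,man_min,man_max,gal_min,gal_max,galnac_min,galnac_max,neuac_min,neuac_max,neugc_min,neugc_max,fuc_min,fuc_max,fuc_site,acetyl_min,acetyl_max
HM,HM,C,0,0,2,6,0,0,0,0,0,0,0,0,0,0,any,0,0
G-HM,glucosylated-HM,C,0,0,7,9,0,0,0,0,0,0,0,0,0,0,any,0,0
PM,PM,C,0,0,-2,1,0,0,0,0,0,0,0,0,0,0,any,0,0
PM-F,PM,C,0,0,-2,1,0,0,0,0,0,0,0,0,1,1,core,0,0
Hy,hybrid,C,1,1,1,3,0,1,0,0,0,0,0,0,0,0,any,0,0
Hy-F,hybrid,C,1,1,1,3,0,1,0,0,0,0,0,0,1,1,core,0,0
Hy-S,hybrid,C,1,1,1,3,0,1,0,0,1,1,0,0,0,0,any,0,2
Hy-SF,hybrid,C,1,1,1,3,0,1,0,0,1,1,0,0,1,1,core,0,2
Hy-G,hybrid,C,1,1,1,3,0,1,0,0,0,0,1,1,0,0,any,0,2
Hy-GF,hybrid,C,1,1,1,3,0,1,0,0,0,0,1,1,1,1,core,0,2
1A-N,complex,C,1,1,0,0,0,1,0,0,0,0,0,0,0,0,any,0,0
1A-NF,complex,C,1,1,0,0,0,1,0,0,0,0,0,0,1,3,any,0,0
1A-S,complex,C,1,1,0,0,0,1,0,0,1,4,0,0,0,0,any,0,2
1A-SF,complex,C,1,1,0,0,0,1,0,0,1,4,0,0,1,3,any,0,2
1A-G,complex,C,1,1,0,0,0,1,0,0,0,0,1,4,0,0,any,0,2
1A-GF,complex,C,1,1,0,0,0,1,0,0,0,0,1,4,1,3,any,0,2
2A-N,complex,C,2,2,0,0,0,2,0,0,0,0,0,0,0,0,any,0,0
2A-NF,complex,C,2,2,0,0,0,2,0,0,0,0,0,0,1,3,any,0,0
2A-S,complex,C,2,2,0,0,0,2,0,0,1,4,0,0,0,0,any,0,2
2A-SF,complex,C,2,2,0,0,0,2,0,0,1,4,0,0,1,3,any,0,2
2A-G,complex,C,2,2,0,0,0,2,0,0,0,0,1,4,0,0,any,0,2
2A-GF,complex,C,2,2,0,0,0,2,0,0,0,0,1,4,1,3,any,0,2
2A-M,complex,C,2,2,0,0,0,2,0,0,1,3,1,3,0,0,any,0,2
2A-MF,complex,C,2,2,0,0,0,2,0,0,1,3,1,3,1,3,any,0,2
3A-N,complex,C,3,3,0,0,0,3,0,0,0,0,0,0,0,0,any,0,0
3A-NF,complex,C,3,3,0,0,0,3,0,0,0,0,0,0,1,3,any,0,0
3A-S,complex,C,3,3,0,0,0,3,0,0,1,4,0,0,0,0,any,0,2
3A-SF,complex,C,3,3,0,0,0,3,0,0,1,4,0,0,1,3,any,0,2
3A-G,complex,C,3,3,0,0,0,3,0,0,0,0,1,4,0,0,any,0,2
3A-GF,complex,C,3,3,0,0,0,3,0,0,0,0,1,4,1,3,any,0,2
3A-M,complex,C,3,3,0,0,0,3,0,0,1,3,1,3,0,0,any,0,2
3A-MF,complex,C,3,3,0,0,0,3,0,0,1,3,1,3,1,3,any,0,2
4A-N,complex,C,4,4,0,0,0,4,0,0,0,0,0,0,0,0,any,0,0
4A-NF,complex,C,4,4,0,0,0,4,0,0,0,0,0,0,1,3,any,0,0
4A-S,complex,C,4,4,0,0,0,4,0,0,1,4,0,0,0,0,any,0,2
4A-SF,complex,C,4,4,0,0,0,4,0,0,1,4,0,0,1,3,any,0,2
4A-G,complex,C,4,4,0,0,0,4,0,0,0,0,1,4,0,0,any,0,2
4A-GF,complex,C,4,4,0,0,0,4,0,0,0,0,1,4,1,3,any,0,2
4A-M,complex,C,4,4,0,0,0,4,0,0,1,3,1,3,0,0,any,0,2
4A-MF,complex,C,4,4,0,0,0,4,0,0,1,3,1,3,1,3,any,0,2
LDN,complex,C,1,4,0,0,0,3,1,3,0,0,0,0,0,3,any,0,0
LDN-S,complex,C,1,4,0,0,0,3,1,3,1,2,0,0,0,3,any,0,0
LDN-GF,complex,C,1,4,0,0,0,3,1,3,0,0,1,1,1,3,any,0,0
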