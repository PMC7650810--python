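dolichol-linked precursor,,N-glycans on nascent protein,,N-glycans on folded protein,,N-glycans,,N-glycans
G-HM,,G-HM,,G-HM,,HM,,HM
C:90000,ra.png,C:80000,ra.png,C:70000,ra.png,C:60000,ra.png,C:50000
ER,,ER,,ER,,ER,,ER
N-glycans,,N-glycans,,N-glycans,,N-glycans,,N-glycans
HM,,Hy,,complex,,complex,,PM
C:20000,ra.png,C:21000,ra.png,C:22000,ra.png,C:22020,ra.png,C:00000
Golgi and later,,Golgi,,Golgi,,Golgi,,Golgi
free N-glycans via OST or PNGase,,free N-glycans,,Gn1 free N-glycans,,Gn1 free N-glycans,,Gn1 free N-glycans
HM,,HM,,HM,,HM,,PM
N2:60000,ra.png,N2:20000,ra.png,N1:20000,ra.png,N1:00000,ra.png,N1:-20000
cytoplasm,,cytoplasm,,cytoplasm,,cytoplasm,,lysosome
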