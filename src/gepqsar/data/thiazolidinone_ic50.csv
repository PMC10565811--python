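compound_id,series,R1,R2,R3,X,A,n,C,ic50_nM
2a,2a-o,H,3-F,,S,,,,32.4
2b,2a-o,H,2-F,,S,,,,34.1
2c,2a-o,H,3-CF3,,S,,,,29.1
2d,2a-o,H,H,,S,,,,15.9
2e,2a-o,H,3-CH3,,S,,,,93.2
2f,2a-o,CH3,2-OCH3,,S,,,,45.1
2g,2a-o,CH3,2-OC2H5,,S,,,,71.6
2h,2a-o,H,3-F-2-OCH3,,S,,,,26.2
2i,2a-o,H,5-F-2-OCH3,,S,,,,71.1
2j,2a-o,H,"2,4-Di-OCH3",,S,,,,8.8
2k,2a-o,H,2-OCH3-5-CH3,,S,,,,90.4
2L,2a-o,H,2-OCH3-5-CH3,,S,,,,300.2
2o,2a-o,H,3-F,,O,,,,319.6
5b,5a-f,H,3-cyclopropyl,H,,,3,,298.8
5c,5a-f,H,4-cyclopropyl,H,,,3,,217.1
5f,5a-f,H,3-ethynyl,H,,,3,,149.2
5g,5a-f,H,3-ethynyl-5-OCH3,H,,,1,,291.6
5h,5a-f,H,2-OCH3,(structure),,,2,,40.8
5i,5a-f,H,2-OCH3,(structure),,,3,,23.5
5j,5a-f,H,2-OCH3,F,,,3,,40.9
5k,5a-f,H,2-OCH3,CH3,,,3,,16.2
5L,5a-f,CH3,4-cyclopropyl,H,,,3,,191.3
5m,5a-f,CH3,3-cyclopropyl,H,,,3,,294.1
6c,6-8,H,,H,,(structure),,(structure),109.7
6g,6-8,H,,H,,(structure),,(structure),19.7
6h,6-8,H,,H,,(structure),,(structure),14.2
7a,6-8,,,H,,(structure),,(structure),78.6
7c,6-8,CH3,,H,,(structure),,(structure),931.9
7e,6-8,H,,H,,(structure),,(structure),285.5
7f,6-8,H,,H,,(structure),,(structure),46.0
7i,6-8,H,,H,,(structure),,(structure),91.7
7j,6-8,H,,H,,(structure),,(structure),97.3
7k,6-8,H,,H,,(structure),,(structure),298.5
8b,6-8,H,,H,,(structure),,(structure),429.5
8c,6-8,H,,H,,(structure),,(structure),60.3
8f,8f-i,,,,,(structure),,,105.4
8g,8f-i,,,,,(structure),,,36.4
8h,8f-i,,,,,(structure),,,33.2
8i,8f-i,,,,,(structure),,,19.6
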