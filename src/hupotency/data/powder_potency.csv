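name,formula,supplier,eta_80,eta_100,eta_120,eta_140
agar,C14H24O9,SA,0.9906,0.9942,0.9968,1.0000
aluminum,Al,AA,1.5110,1.3570,1.2710,1.2190
ammonium bicarbonate,NH5CO3,SA,0.9687,0.9752,0.9776,0.9815
ammonium phosphate monobasic,NH6PO4,SA,1.2760,1.2010,1.1590,1.1330
calcium carbonate,CaCO3,AA,2.1560,1.8590,1.6900,1.5870
calcium chloride,CaCl2,SA,2.8090,2.3400,2.0700,1.9050
calcium phosphate,Ca3P2O8,SA,2.1910,1.8810,1.7040,1.5940
calcium sulfate dihydrate,CaSO6H4,SA,1.9970,1.7500,1.6070,1.5220
graphite,C,AA,0.8808,0.9047,0.9230,0.9365
hydroxyapatite,Ca5P3O13H,SA,2.2670,1.9430,1.7590,1.6500
kaolin,Al2Si2O9H4,SA,1.4120,1.3090,1.2490,1.2160
magnesium carbonate,MgCO3,SA,1.1350,1.1010,1.0910,1.0870
magnesium chloride hexahydrate,MgCl2H12O6,SA,1.6180,1.4610,1.3710,1.3160
magnesium nitrate hexahydrate,MgN2H12O12,SA,1.0300,1.0210,1.0110,1.0100
magnesium oxide,MgO,SA,1.3080,1.2290,1.1890,1.1640
potassium carbonate,K2CO3,SA,2.1060,1.8120,1.6400,1.5370
potassium chloride,KCl,SA,2.6720,2.2340,1.9820,1.8250
potassium nitrate,KNO3,AA,1.8270,1.6010,1.4750,1.3970
potassium phosphate dibasic,K2HPO4,SA,2.2200,1.9040,1.7250,1.6150
potassium phosphate monobasic,KH2PO4,SA,1.8050,1.5860,1.4600,1.3830
potassium sulfate,K2SO4,SA,2.1860,1.8770,1.7030,1.5930
silicon,Si,AA,1.7650,1.5580,1.4440,1.3720
sodium acetate,NaC2H3O2,SA,1.0330,1.0160,1.0070,1.0030
sodium bicarbonate,NaCHO3,SA,1.0230,1.0000,0.9875,0.9806
sodium carbonate,Na2CO3,SA,1.0720,1.0360,1.0170,1.0070
sodium chloride,NaCl,SA,1.9240,1.6660,1.5220,1.4320
sodium phosphate dibasic,Na2HPO4,SA,1.2770,1.1900,1.1410,1.1120
sulfur,S,AA,2.2460,1.9270,1.7430,1.6290
tricalcium phosphate,Ca3P2O8,SA,2.3720,2.0390,1.8480,1.7320
urea,CH4N2O,SA,0.9543,0.9657,0.9712,0.9775
water,H2O,TM,1.0290,1.0310,1.0320,1.0340
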