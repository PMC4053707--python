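day,cod_balance_percent,acetate,butyrate,propionate,ethanol,methane,biomass
45,100,1.52,0.02,0.09,0,1.14,0.38
52,100,1.44,0.02,0.09,0,1.22,0.35
70,93,1.51,0.01,0.07,0,0.99,0.36
89,98,1.49,0.01,0.06,0.17,0.89,0.47
100,100,1.61,0.01,0.07,0.03,0.98,0.40
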