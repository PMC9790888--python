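extender,water_mL,tris_mL,egg_yolk_mL,milk_mL,fructose_mg,trehalose_mg,clc_mg,glutathione_uL,melatonin_uL,ngf_ng,glycerol_mL,ethylene_glycol_mL
1,1.17,6.31,1.88,0.07,44.8,162.3,6.9,6.1,8.72,45.2,0.61,0.0
2,1.22,7.28,1.87,0.05,0.09,138.3,6.7,5.6,10.7,213.2,0.61,0.0
3,0.57,6.68,2.0,0.17,46.1,147.0,5.1,3.1,8.7,211.2,0.65,0.07
4,0.16,7.3,1.87,0.3,0.43,100.0,6.3,5.1,9.4,209.2,0.64,0.1
5,1.16,5.8,2.0,0.01,59.8,142.3,5.1,5.0,9.2,230.2,0.61,0.0
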