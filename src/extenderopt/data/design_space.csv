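name,unit,lower,upper,reference,active
tris,percent v/v,0,50,50,1
egg_yolk,percent v/v,0,20,20,1
milk,percent v/v,0,15,15,1
fructose,percent w/v,0,1.25,1.25,1
glycerol,percent v/v,0,7,7,1
ethylene_glycol,percent v/v,0,6.75,6.75,1
trehalose,mM,0,100,100,1
clc,mg/mL,0.5,1,1,1
glutathione,mM,0.5,0.5,0.5,1
melatonin,mM,2,3,3,1
ngf,mg/mL,0,0.5,0.5,1
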