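name,dm,cp,ndf,adf,omd,starch,ee,ne_mcal,p
own_forage,0.88,0.10,0.55,0.33,0.62,0.05,0.02,1.25,0.0025
purchased_forage,0.88,0.12,0.50,0.32,0.64,0.05,0.02,1.30,0.0025
concentrate,0.89,0.18,0.22,0.10,0.80,0.40,0.03,1.80,0.0045
concentrate_fibrous,0.89,0.16,0.38,0.22,0.70,0.18,0.03,1.55,0.0050
soybean,0.88,0.44,0.14,0.08,0.88,0.06,0.02,2.05,0.0062
peas,0.88,0.23,0.16,0.08,0.85,0.45,0.015,1.95,0.0042
pasture,0.25,0.14,0.48,0.28,0.68,0.03,0.03,1.40,0.0030
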