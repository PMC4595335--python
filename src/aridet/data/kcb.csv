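crop,kcb_ini,kcb_mid,kcb_end
Spring wheat,0.30,1.27,0.82
Summer maize,0.30,1.19,0.80
Potato,0.15,1.10,0.65
Soybean,0.15,1.10,0.30
Beet,0.15,1.10,0.95
Chili,0.15,1.10,0.80
Watermelon,0.15,1.05,0.75
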