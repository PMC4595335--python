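crop,current,scenario_1,scenario_2
Spring wheat,40,20,40
Summer maize,30,30,9.5
Potato,12,5,16.8
Soybean,3,10,5
Beet,5,5,5
Chili,10,10,13.8
Watermelon,0,20,9.9
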