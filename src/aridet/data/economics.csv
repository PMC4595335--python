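crop,yield_kg_hm2,price_yuan_kg,unit_input_yuan_hm2
Spring wheat,6510,2.1,9525
Summer maize,9900,2.0,13610
Potato,33110,0.8,10800
Soybean,2100,3.2,5400
Beet,31500,0.5,10500
Chili,18750,1.1,16500
Watermelon,34872,0.6,12750
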