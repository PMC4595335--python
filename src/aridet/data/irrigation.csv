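crop,month,day,quota_mm
Spring wheat,5,6,105
Spring wheat,5,26,105
Spring wheat,6,13,105
Spring wheat,7,6,97.5
Summer maize,6,13,105
Summer maize,7,6,112.5
Summer maize,8,4,112.5
Summer maize,8,24,105
Potato,5,27,97.5
Potato,6,16,97.5
Potato,7,7,97.5
Potato,7,30,90
Soybean,5,25,90
Soybean,6,15,97.5
Soybean,7,6,105
Soybean,8,4,105
Beet,5,15,97.5
Beet,6,4,105
Beet,7,1,105
Beet,8,6,105
Chili,5,20,97.5
Chili,6,15,97.5
Chili,7,1,97.5
Chili,7,28,97.5
Watermelon,5,9,75
Watermelon,5,27,82.5
Watermelon,6,16,75
Watermelon,7,7,75
Watermelon,7,26,67.5
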