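# ASSUMED phenology for the Shiyang River basin (Wuwei) cropping calendar.
# These values are package assumptions, not measured district data: planting
# dates and FAO-56 stage lengths were chosen so that every scheduled irrigation
# date falls inside the crop's growing season and the calendar matches the
# region's documented spring-sown cropping pattern.
crop,plant_month,plant_day,l_ini,l_dev,l_mid,l_late,height_max_m,lai_max,root_depth_max_mm
Spring wheat,3,25,25,30,45,25,1.0,4.0,1000
Summer maize,4,20,25,40,50,30,2.0,5.0,1000
Potato,4,25,30,35,50,30,0.6,4.0,600
Soybean,4,28,20,35,60,25,0.8,4.5,800
Beet,4,10,30,45,60,40,0.5,4.0,800
Chili,4,28,30,40,55,25,0.6,3.5,600
Watermelon,4,22,20,30,40,30,0.4,3.0,800
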