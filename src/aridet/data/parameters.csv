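parameter,definition,rank,range_min,range_max,calibrated,process
esco,Soil evaporation compensation factor,1,0.0,1.0,0.875,Evaporation
canmx,Maximum canopy interception,2,0.0,30.0,9.853,Evaporation
gw_revap,Shallow groundwater re-evaporation coefficient,3,0.02,0.2,0.115,Groundwater
epco,Plant absorb compensation factor,4,0.0,1.0,0.827,Evaporation
sol_awc_scale,Soil available water,5,-0.5,0.5,0,Soil
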