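# NEWS weight table (RCPL 2012 chart bands).
# Bounds are inclusive at recording precision (temperature 0.1 degC, others integer);
# an empty bound is open-ended. Categorical items use ordinal encodings:
# supplemental_oxygen 0=air 1=oxygen; consciousness A=0 V=1 P=2 U=3.
parameter,lower,upper,weight,scale,oxygen_state
respiratory_rate,,8,3,,any
respiratory_rate,9,11,1,,any
respiratory_rate,12,20,0,,any
respiratory_rate,21,24,2,,any
respiratory_rate,25,,3,,any
temperature,,35.0,3,,any
temperature,35.1,36.0,1,,any
temperature,36.1,38.0,0,,any
temperature,38.1,39.0,1,,any
temperature,39.1,,2,,any
systolic_bp,,90,3,,any
systolic_bp,91,100,2,,any
systolic_bp,101,110,1,,any
systolic_bp,111,219,0,,any
systolic_bp,220,,3,,any
heart_rate,,40,3,,any
heart_rate,41,50,1,,any
heart_rate,51,90,0,,any
heart_rate,91,110,1,,any
heart_rate,111,130,2,,any
heart_rate,131,,3,,any
spo2,,91,3,1,any
spo2,92,93,2,1,any
spo2,94,95,1,1,any
spo2,96,,0,1,any
supplemental_oxygen,0,0,0,,any
supplemental_oxygen,1,1,2,,any
consciousness,0,0,0,,any
consciousness,1,3,3,,any
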