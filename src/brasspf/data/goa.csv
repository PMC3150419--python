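age_lower,asfr_interval,ceb_mean
15,0.025,1.400
20,0.295,2.234
25,0.550,2.466
30,0.370,2.744
35,0.140,3.282
40,0.035,4.066
45,0.005,4.455
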