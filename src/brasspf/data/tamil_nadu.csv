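age_lower,asfr_interval,ceb_mean
15,0.155,1.453
20,0.895,1.976
25,0.620,2.601
30,0.225,3.007
35,0.055,3.525
40,0.015,4.249
45,0.005,4.896
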