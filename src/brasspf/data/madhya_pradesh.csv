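age_lower,asfr_interval,ceb_mean
15,0.440,1.565
20,1.375,2.825
25,1.070,4.086
30,0.630,5.025
35,0.315,5.763
40,0.140,6.141
45,0.025,6.626
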