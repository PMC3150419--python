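age_lower,asfr_interval,ceb_mean
15,0.200,1.611
20,1.240,2.728
25,1.355,4.030
30,0.990,5.355
35,0.575,6.012
40,0.310,6.702
45,0.115,6.854
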