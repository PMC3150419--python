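age_lower,asfr_interval,ceb_mean
15,0.275,1.470
20,1.210,3.500
25,1.155,3.910
30,0.890,5.040
35,0.495,5.590
40,0.260,6.210
45,0.075,6.450
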