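id,origin,is_hit,pec50,emax_percent,rank_cluster,rank_library
beta-PEA,reference,True,6.6,100.0,,
Ulotaront,reference,True,6.1,96.4,,
13,af,True,5.5,51.8,2938,35310
14,af,True,5.1,54.3,1098,109532
15,af,True,5.2,57.5,311,56230
16,af,True,5.8,61.9,4001,44811
17,af,True,5.2,67.8,1017,865757
18,af,True,6.2,68.7,84,437792
19,af,True,5.4,74.5,573,382074
20,af,True,5.4,74.5,151,25997
21,af,True,5.5,75.2,555,195139
22,af,True,5.5,78.5,3272,195139
23,af,True,5.4,79.2,1528,37423
24,af,True,5.8,81.4,668,18592
25,af,True,6.0,95.3,717,85960
26,af,True,6.0,95.5,3040,212223
27,af,True,6.6,98.7,3060,65537
28,af,True,6.4,102.6,187,22718
29,af,True,6.8,105.7,381,7957
30,af,True,7.5,112.5,963,22595
af_nonhit_01,af,False,,,,
af_nonhit_02,af,False,,,,
af_nonhit_03,af,False,,,,
af_nonhit_04,af,False,,,,
af_nonhit_05,af,False,,,,
af_nonhit_06,af,False,,,,
af_nonhit_07,af,False,,,,
af_nonhit_08,af,False,,,,
af_nonhit_09,af,False,,,,
af_nonhit_10,af,False,,,,
af_nonhit_11,af,False,,,,
af_nonhit_12,af,False,,,,
56,hm,True,4.9,63.0,2811,467247
57,hm,True,5.3,73.2,290,118716
58,hm,True,5.1,78.4,3350,
59,hm,True,5.2,78.8,550,12903
60,hm,True,5.5,79.9,1877,165473
61,hm,True,5.3,80.3,1359,39818
62,hm,True,6.5,107.4,3728,469
hm_nonhit_01,hm,False,,,,
hm_nonhit_02,hm,False,,,,
hm_nonhit_03,hm,False,,,,
hm_nonhit_04,hm,False,,,,
hm_nonhit_05,hm,False,,,,
hm_nonhit_06,hm,False,,,,
hm_nonhit_07,hm,False,,,,
hm_nonhit_08,hm,False,,,,
hm_nonhit_09,hm,False,,,,
hm_nonhit_10,hm,False,,,,
hm_nonhit_11,hm,False,,,,
hm_nonhit_12,hm,False,,,,
hm_nonhit_13,hm,False,,,,
hm_nonhit_14,hm,False,,,,
hm_nonhit_15,hm,False,,,,
hm_nonhit_16,hm,False,,,,
hm_nonhit_17,hm,False,,,,
hm_nonhit_18,hm,False,,,,
hm_nonhit_19,hm,False,,,,
hm_nonhit_20,hm,False,,,,
hm_nonhit_21,hm,False,,,,
hm_nonhit_22,hm,False,,,,
hm_nonhit_23,hm,False,,,,
hm_nonhit_24,hm,False,,,,
hm_nonhit_25,hm,False,,,,
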