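row,key,Germany,Greece,Hungary,Poland,Romania,Spain
1,addresses_attempted,10325,3537,2754,3421,4490,4114
2,addresses_contacted,8259,2856,2404,3028,2778,3853
3,eligibility_determined,3086,1295,1791,2154,2065,2451
4,no_eligible,1982,466,972,1163,1134,1509
5,with_eligible,1104,829,819,991,931,942
6,households_with_selection,1085,823,809,976,911,936
9,individuals_selected,1425,1116,1078,1265,1254,1234
10,individual_refusals,200,91,64,227,232,219
11,completed_interviews,1003,1000,1000,1006,1003,1001
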