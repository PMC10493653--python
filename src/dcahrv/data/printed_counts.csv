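table,row,printed_chi2,g1_yes,g1_n,g2_yes,g2_n,g3_yes,g3_n
demographics,sex_male,0.113,13,45,16,50,15,50
demographics,hypertension,0.255,7,45,6,50,7,50
demographics,hyperlipidemia,0.250,9,45,9,50,11,50
demographics,diabetes_mellitus,0.368,5,45,4,50,4,50
demographics,current_smoking,0.523,10,45,10,50,13,50
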