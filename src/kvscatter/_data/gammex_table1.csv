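insert,electron_density,orig_no_bolus,orig_no_bolus_std,orig_bolus,orig_bolus_std,proc_no_bolus,proc_no_bolus_std,proc_bolus,proc_bolus_std
LN-lung 300,0.289,27,12,134,12,33,19,97,22
Lung 450,0.403,135,13,190,10,97,18,218,19
Adipose,0.924,305,16,258,10,397,26,441,21
Breast,0.956,376,24,275,13,438,31,394,27
Solid Water 1,0.989,435,22,334,14,509,30,515,26
Solid Water 2,0.989,438,12,377,13,430,15,426,19
Solid Water 3,0.989,372,14,264,11,403,25,349,24
Solid Water 4,0.989,360,12,320,11,432,14,423,24
Water,1,292,28,247,17,406,26,389,23
Brain,1.049,413,10,300,7,501,31,480,32
Liver,1.064,389,18,308,15,497,17,417,19
Inner Bone,1.096,523,19,421,17,594,25,563,19
B-200,1.106,440,19,345,18,580,19,534,18
CB2 (30%),1.279,516,15,330,14,700,27,588,30
CB2 (50%),1.470,749,36,424,13,1078,45,793,43
Cortical Bone,1.695,996,51,511,19,1269,43,920,29
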