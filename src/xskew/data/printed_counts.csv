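# Published cross-tabulation counts (events k out of n informative subjects)
# for the esophageal-carcinoma SXCI survey; consumed by `xskew reproduce-paper`.
# threshold: corrected-ratio cutoff defining SXCI (3 = moderate, 10 = stringent).
table,group,threshold,k,n
overall,informative,3,52,356
overall,informative,10,19,356
three_group,neonates,3,2,46
three_group,16-50,3,13,166
three_group,51-96,3,37,144
three_group,neonates,10,1,46
three_group,16-50,10,2,166
three_group,51-96,10,16,144
five_group,neonates,3,2,46
five_group,16-30,3,3,61
five_group,31-50,3,10,105
five_group,51-70,3,7,65
five_group,71-96,3,30,79
table1,patients_le40,3,5,14
table1,controls_le40,3,13,170
table1,patients_gt40,3,8,120
table1,controls_gt40,3,12,115
table1,patients_all,3,13,134
table1,controls_all,3,25,285
table1,patients_le40,10,1,14
table1,controls_le40,10,2,170
table1,patients_gt40,10,6,120
table1,controls_gt40,10,6,115
table1,patients_all,10,7,134
table1,controls_all,10,8,285
stage,I,3,7,88
stage,IIA,3,2,10
stage,IIB,3,1,10
stage,III,3,2,15
stage,IV,3,1,11
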