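experiment_id,host_id,design_kind,choosing_sex,choosing_species,pairs_ShSh,pairs_SbSb,pairs_ShSb,pairs_SbSh,single_M_Sh,single_M_Sb,single_F_Sh,single_F_Sb
exp1,1,limited_choice,M,Sh,11,,14,,0,,20,9
exp1,2,limited_choice,M,Sh,11,,22,,0,,15,11
exp1,3,limited_choice,M,Sh,14,,16,,0,,25,4
exp1,4,limited_choice,M,Sh,9,,6,,0,,36,26
exp1,5,limited_choice,M,Sh,10,,10,,0,,41,15
exp2,1,limited_choice,F,Sh,10,,,2,7,5,0,
exp2,2,limited_choice,F,Sh,6,,,1,0,1,0,
exp2,3,limited_choice,F,Sh,12,,,3,11,10,0,
exp2,4,limited_choice,F,Sh,16,,,3,6,2,0,
exp2,5,limited_choice,F,Sh,12,,,13,11,12,0,
exp3,2,limited_choice,M,Sb,,4,,0,,0,55,46
exp3,3,limited_choice,M,Sb,,2,,1,,0,32,22
exp4,1,limited_choice,F,Sb,,15,17,,14,4,,0
exp4,2,limited_choice,F,Sb,,10,25,,19,2,,0
exp4,3,limited_choice,F,Sb,,3,8,,13,4,,0
exp4,4,limited_choice,F,Sb,,9,15,,19,8,,0
exp4,5,limited_choice,F,Sb,,49,15,,5,18,,0
exp5,1,full_choice,,,1,,5,4,8,5,4,9
exp5,2,full_choice,,,8,2,5,1,8,3,23,8
exp5,3,full_choice,,,7,2,1,2,6,5,19,11
exp5,4,full_choice,,,4,6,3,1,10,4,13,11
exp5,5,full_choice,,,5,1,6,2,20,3,17,16
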