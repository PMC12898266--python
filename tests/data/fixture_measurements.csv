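patient_id,cm_name,date,value
P1,SBP,2010-01-01,130
P1,SBP,2010-01-11,150
P1,SBP,2010-01-21,160
P1,SBP,2010-01-31,135
P2,A1c,2015-05-05,8.5
P3,LDL,2012-01-01,150
P3,LDL,2012-03-01,120
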