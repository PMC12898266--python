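patient_id,index_date,death60,age,charl_2yr,charl_ever,elix_2yr,elix_ever
P1,2010-02-14,0,62.0,1,2,1,2
P2,2015-06-05,1,71.5,2,4,3,5
P3,2012-03-20,0,55.0,0,1,0,1
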