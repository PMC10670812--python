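variable,category,all,cb,no_cb
site,right,33,26,7
site,left,37,29,8
quadrant,central,7,5,2
quadrant,upper-inner,11,9,2
quadrant,lower-inner,7,6,1
quadrant,upper-outer,28,23,5
quadrant,lower-outer,16,11,5
quadrant,unspecified,1,1,0
histology,ductal,62,50,12
histology,lobular,5,3,2
histology,papillary,1,0,1
histology,mucinous,1,1,0
histology,apocrine,1,1,0
subtype,A,13,12,1
subtype,B,36,26,10
subtype,H,6,4,2
subtype,N,15,13,2
t_stage,1,21,19,2
t_stage,2,34,27,7
t_stage,3,2,1,1
t_stage,4,13,8,5
n_stage,0,19,17,2
n_stage,1,34,26,8
n_stage,2,6,4,2
n_stage,3,11,8,3
m_stage,0,58,51,7
m_stage,1,12,4,8
margin,sharp,10,7,3
margin,irregular,55,44,11
margin,spiculated,5,4,1
morphology,solid,66,53,13
morphology,inflammatory,4,2,2
death,0,65,55,10
death,1,5,0,5
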