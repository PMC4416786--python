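drug,genotype,kp,v_u_brain,f_u_plasma
digoxin,C57BL6_WT,0.05,44.8,0.594
digoxin,HMDR1,0.11,44.8,0.607
verapamil,C57BL6_WT,0.6,48.2,0.115
verapamil,HMDR1,9,48.2,0.117
docetaxel,C57BL6_WT,0.09,789,0.053
docetaxel,HMDR1,0.13,789,0.052
oxycodone,C57BL6_WT,4.8,3.75,0.681
oxycodone,HMDR1,7.7,3.75,0.681
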