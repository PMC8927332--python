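sample_id,batch,cov
S00,a,x
S01,a,y
S02,a,x
S03,a,y
S04,a,x
S05,a,y
S06,a,x
S07,a,y
S08,a,x
S09,a,y
S10,a,x
S11,b,y
S12,b,x
S13,b,y
S14,b,x
S15,b,y
S16,b,x
S17,b,y
S18,b,x
S19,b,y
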