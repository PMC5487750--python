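subject_id,r1,r2,r3,r4
s0,9,2,5,8
s1,6,1,3,2
s2,8,4,6,8
s3,7,1,2,6
s4,10,5,6,9
s5,6,2,4,7
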