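source,sex,age_lo,age_hi,intercept,c_age,c_height,c_weight
mckay,female,3,20,-54.9,1.1,5.5,-2.7
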