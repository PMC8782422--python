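assessment_id,sex,age_lo,age_hi,raw_value_lo,raw_value_hi,score
ts_eyes_open,any,6,80,0,2,3
ts_eyes_open,any,6,80,2,5,2
ts_eyes_open,any,6,80,5,8,1
ts_eyes_open,any,6,80,8,inf,0
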