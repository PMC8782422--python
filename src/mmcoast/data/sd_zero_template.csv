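assessment_id,sex,age_lo,age_hi,raw_value_lo,raw_value_hi,score
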