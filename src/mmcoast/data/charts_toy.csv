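chart_id,lower,upper,score
zscore_chart_A,,-4,3
zscore_chart_A,-4,-3,2
zscore_chart_A,-3,-2,1
zscore_chart_A,-2,,0
decrement_chart_B,,-39,3
decrement_chart_B,-39,-26,2
decrement_chart_B,-26,-13,1
decrement_chart_B,-13,,0
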