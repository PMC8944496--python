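class,coefficient
lactating_high,0.15
lactating_medium,0.15
lactating_low,0.15
non_lactating,0.15
studs,0.15
replacement_0_4,0.09
replacement_4_12,0.09
offspring,0.05
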