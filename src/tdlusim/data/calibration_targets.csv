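phase,target_mean,tolerance
follicular,0.05,0.01
inbetween,0.04,0.01
luteal,0.07,0.02
regulatory_all,0.055,0.01
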