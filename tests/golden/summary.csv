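condition,n_total,n_ifn,pct_ifn,n_top
disease,15,12,80.0,12
immunised,8,8,100.0,8
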