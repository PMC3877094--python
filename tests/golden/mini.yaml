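n_common: 6
n_disease_specific: 5
n_immunisation_specific: 2
n_non_ifn_de: 3
n_null: 12
n_absent: 3
probes_per_set: 11
n_baseline: 3
n_day7: 3
n_disease: 3
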