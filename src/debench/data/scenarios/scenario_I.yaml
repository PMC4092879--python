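name: I
n_per_group: 10
prop_de: 0.1
up_down_ratio:
- 1
- 1
fc_lower_bound: 1.5
depth_lower_bound: 5
n_genes: 10000
n_datasets: 30
gamma_shape: 0.87
gamma_rate: 1.36
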