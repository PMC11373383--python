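# Old migration (ancient divergence of the two sampled demes).
id: D4
confounder: migration
present_size: 50000
join_time: 3
selection_coefficient: 0.02
sweep_start: 0.005
sample_split: 0.5
theta: 200
rho: 200
sequence_length: 100000
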