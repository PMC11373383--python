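# Recent migration (two demes joining) scenario.  The sample is drawn
# symmetrically from two demes of size N0 that share an ancestral
# population older than join_time.
id: D3
confounder: migration
present_size: 50000
join_time: 0.003
selection_coefficient: 0.02
sweep_start: 0.005
sample_split: 0.5       # fraction of the sample drawn from deme A
theta: 200
rho: 200
sequence_length: 100000
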