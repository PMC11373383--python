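# Severe bottleneck scenario.
id: D2
confounder: bottleneck
present_size: 50000
severity: 0.005
duration: 0.002
onset: 0.01
selection_coefficient: 0.02
sweep_start: 0.016
# theta/rho/region length chosen so replicates comfortably exceed 128
# segregating sites despite the bottleneck-driven loss of diversity.
theta: 200
rho: 200
sequence_length: 100000
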