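# Mild bottleneck scenario.
# Times are in coalescent units of 4*N0 generations (N0 = present_size
# diploids); sizes are relative to N0.
id: D1
confounder: bottleneck
present_size: 50000
severity: 0.5           # population size during the bottleneck, relative to N0
duration: 0.001
onset: 0.1
selection_coefficient: 0.02
sweep_start: 0.016      # time since fixation of the beneficial allele
# theta/rho/region length are not part of the scenario definition and were
# chosen so replicates comfortably exceed 128 segregating sites.
theta: 200
rho: 200
sequence_length: 100000
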