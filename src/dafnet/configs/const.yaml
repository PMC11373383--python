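# Constant-size control population (no confounder); used as the neutral
# baseline in diagnostics and small training exercises.
id: CONST
confounder: none
present_size: 50000
selection_coefficient: 0.02
sweep_start: 0.016
theta: 200
rho: 200
sequence_length: 100000
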