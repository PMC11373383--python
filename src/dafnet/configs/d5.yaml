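# Low-intensity recombination hotspot: a central 5 kb segment with a
# 2-fold elevated recombination rate.
id: D5
confounder: hotspot
present_size: 50000
hotspot_intensity: 2
hotspot_span: 5000
selection_coefficient: 0.02
sweep_start: 0.005
theta: 2000
rho: 2000
sequence_length: 100000
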