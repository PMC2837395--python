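# Full-scale fluctuation-rate sweep under stationary-phase stress.
# Run with r in {0.01, 0.001, 0.0001, 0} (override r per run); concentrations
# start at unequal, post-adaptation-like values so that the four conditions
# are comparable.
protocol: stationary_phase
t_apply: 20000
t_max: 25000
cap: 5000
seed_pop: 500
n_structures: 10000
structure_source: full
record_every: 25
r: 0.01
initial_C: [0.125, 0.125, 0.125, 0.025]
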