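# Full-scale constant-fitness drift control: sample mutator frequency
# every 25 steps from t = 8000 to t = 10000 (80 samples per run), 50
# replicates per fitness value (CLI: mutatorsim drift --replicates 50).
protocol: none
t_max: 10000
cap: 5000
seed_pop: 500
n_structures: 10000
structure_source: full
record_every: 25
initial_C: [0.125, 0.125, 0.125, 0.025]
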