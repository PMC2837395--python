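# Full-scale stationary-phase protocol: b0 drops threefold at t = 20000.
# Cluster-scale: run 100 replicates (vary master_seed) for ensemble statistics.
protocol: stationary_phase
t_apply: 20000
t_max: 25000
cap: 5000
seed_pop: 500
n_structures: 10000
structure_source: full
record_every: 25
b0: 707.445
b0_stationary: 235.815
d: 0.005
r: 0.01
sigma: 100.0
C0: 0.4
C0_starvation: 0.04
m_min: 0.0001
m_max: 0.1
T: 0.85
T_high: 1.00
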