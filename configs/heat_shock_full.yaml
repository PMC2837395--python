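# Full-scale heat-shock protocol: T 0.85 -> 1.00 at t = 20000.
# Cluster-scale: the published ensemble is 100 independent runs of this
# configuration (vary master_seed); a single run takes hours on one CPU.
protocol: heat_shock
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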