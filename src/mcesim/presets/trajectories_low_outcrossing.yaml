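# Trajectory ensemble: weak pollinator-mediated outcrossing (p = 0.1),
# autonomous selfing capacity 80%, per-replicate polyploid fitness deviation
# drawn from N(0, 2.5) ovules.
q0: 0.05
n_adults: 500
p_outcross: 0.1
a_selfing: 0.8
timing_mode: delayed
c_clonal: 0.0
u_ug: 0.0
t3_fitness: 0.0
sigma_fitness: 2.5
n_generations: 200
n_replicates: 100
base_seed: 0
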