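# Base scenario for the autonomous-selfing x outcrossing establishment
# sweep; triploid fitness and unreduced gametes are forced to 0 per cell.
q0: 0.05
n_adults: 500
timing_mode: delayed
c_clonal: 0.0
u_ug: 0.0
t3_fitness: 0.0
sigma_fitness: 2.5
n_generations: 200
n_replicates: 100
base_seed: 0
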