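# Obligate outcrossing with a complete triploid block: the classic
# frequency-dependent exclusion of a rare tetraploid.
q0: 0.05
n_adults: 500
p_outcross: 1.0
a_selfing: 0.0
c_clonal: 0.0
u_ug: 0.0
t3_fitness: 0.0
alpha_assort: 0.0
sigma_fitness: 0.0
n_generations: 200
n_replicates: 500
base_seed: 0
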