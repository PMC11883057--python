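# Mating-neutral control: all ovules autonomously selfed, no clonality, no
# fitness deviation.  Establishment probability equals the neutral fixation
# probability q0.
q0: 0.05
n_adults: 100
p_outcross: 0.0
a_selfing: 1.0
c_clonal: 0.0
sigma_fitness: 0.0
t3_fitness: 0.0
u_ug: 0.0
n_generations: 200
n_replicates: 2000
base_seed: 0
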