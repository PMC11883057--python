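# Base scenario for the triploid-fitness x unreduced-gametes x uniparental
# surface.  Mating parameters (a_selfing, p_outcross, c_clonal) are set per
# cell by the uniparental-axis mapping; no fitness deviation, so the surface
# isolates the mating mechanics against the neutral-drift baseline q0.
q0: 0.05
n_adults: 100
sigma_fitness: 0.0
n_generations: 200
n_replicates: 200
base_seed: 0
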