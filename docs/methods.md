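# Methods

## Model structure

`mcesim` simulates a constant-size, non-overlapping-generation population of
`n_adults` plants, each characterized by a cytotype (2x, 3x, 4x) and a genet
identity. The life cycle per generation is: fecundity allocation → ovule fate
resolution → pollen-donor sampling → gamete draws → zygote formation →
viability weighting → recruitment of exactly `n_adults` adults. All
stochastic operations of one replicate share a single PCG64 stream seeded
`base_seed + replicate_index`; nothing uses global random state.

### Fecundity and clonality

Each adult's expected ovule output is `B = fecundity_b` (default 10),
split between clonal propagules (mean `c·B`) and sexual ovules (mean
`(1−c)·B`). Realized counts are Poisson draws with those means: the model
needs integer litter sizes and Poisson is the minimal-assumption count
distribution for independent ovule initiations. Clonal offspring copy the
parent's cytotype and genet id; triploid ramets carry the triploid survival
weight `t3_fitness` like any other triploid recruit.

Tetraploid adults use `max(0, B + δ)`, where the deviation `δ ~ N(0,
sigma_fitness)` is drawn **once per replicate**: each run represents a single
polyploidization event whose fitness consequences (genomic shock, gigas
effects) are fixed at origin. Across the ensemble the expected deviation is
zero, so diploids and polyploids have equal mean fitness while individual
runs differ — which is what produces the spread of trajectories and the
possibility of establishment under weak MCE. The deviation applies to 4x
adults only; triploid performance is controlled separately and explicitly by
`t3_fitness`/`f3_fertility`. `sigma_fitness` is in ovule-count units (an
additive offset on `B`).

### Ovule fates and selfing timing

With outcross-pollen probability `p` and autonomous selfing capacity `a`,
the per-ovule fate distribution depends on the order of events:

| mode | P(outcross) | P(self) | P(unfertilized) |
|---|---|---|---|
| `delayed` (default) | `p` | `(1−p)a` | `(1−p)(1−a)` |
| `prior` | `(1−a)p` | `a` | `(1−a)(1−p)` |
| `competing` | mean of the two | mean | `(1−p)(1−a)` |

`delayed` models selfing as reproductive assurance: outcross pollen claims
ovules first, which is why high pollinator effectiveness suppresses the
selfing escape route even in highly selfing-capable polyploids. `competing`
draws one of the two orderings per ovule with probability ½, which is
marginally identical to averaging the fate probabilities (ovules are
independent); the implementation uses the closed form. Unfertilized ovules
are lost without resource reallocation.

### Donors, gametes, zygotes

Outcross donors are sampled with weight `1 + alpha_assort` for individuals
of the mother's cytotype and 1 otherwise. The mother is in the donor pool (a
self-draw is autogamy) and so are ramets of her genet (geitonogamy); both
classes are viable only if the maternal cytotype is self-compatible
(`self_compatible`, default true for all cytotypes). Autonomously selfed
ovules draw both gametes independently from the mother's own gamete
distribution.

Gamete distributions: 2x → 1n (`1−u`), 2n (`u`); 4x → 2n (`1−u`), 4n (`u`);
3x → functional with probability `f3_fertility`, then 1n/2n/3n with the
`g3_spectrum` mass (default 0.25/0.375/0.375, placing three times as much
mass on unreduced 2n+3n classes as on reduced 1n gametes, consistent with
the strong meiotic irregularity of triploids). Zygote ploidy is the gamete
sum; 2x and 4x zygotes have survival weight 1, 3x zygotes `t3_fitness`, and
anything above `max_ploidy_viable` (capped at 4 — pentaploid and higher
adults are outside the model's state space, so the validator rejects larger
values) dies.

### Recruitment

The next generation is a weight-proportional multinomial sample of
`n_adults` from the viable offspring pool (sampling with replacement,
Wright–Fisher style). This was a deliberate choice over weighted sampling
*without* replacement: successive weighted sampling has inclusion
probabilities that are not proportional to the weights, which would bias the
realized cytotype distribution away from the exact mean-field expectation
whenever mixed weights (`t3` vs 1) are present, and the multinomial scheme
is the standard population-genetic regulation model. Fixation probabilities
of neutral variants are unaffected (exchangeability). An empty pool is a
global reproductive failure and terminates the replicate.

### Outcome classification

A replicate stops early when the polyploid lineage (3x + 4x) is extinct and
cannot regenerate (`u_ug = 0`), or when the tetraploid is fixed; otherwise
it runs `n_generations`. Terminal states: *excluded* (no 3x/4x left),
*established* (4x fixed, or tracked polyploid frequency ≥
`establish_threshold`, default 0.5 — a threshold is needed because slow
drift need not absorb within the horizon), *persisting*, or
*global_extinction*. By default the tracked polyploid frequency is the 4x
frequency alone (`polyploid_includes_3x` switches to 3x + 4x). Ensemble mean
trajectories extend absorbed replicates at their absorbing state so the mean
is defined at every generation.

## The mean-field oracle

`oracle.expected_offspring_distribution` computes the exact one-generation
map of cytotype frequencies in an infinite population by enumerating every
(maternal cytotype × fate × donor cytotype × maternal gamete × paternal
gamete) path with its probability and viability weight, plus the clonal
mass. It deliberately ignores `sigma_fitness` and all finite-size sampling:
it is a validator of the mating mechanics, not a second simulator. At mean
field a single genet has measure zero, so geitonogamy is indistinguishable
from autogamy and the donor distribution excludes the mother as an
individual — an expected, documented difference from the agent-based model
of order 1/N.

Under obligate outcrossing with a complete triploid block the map reduces to
the classic frequency-dependent recursion `f4′ = f4²/(f4² + (1−f4)²)`
(verified to 1e−12), with the unstable equilibrium at 0.5.
`unstable_threshold` locates the interior unstable fixed point by bracketing
the sign change of `f4′ − f4` on a 1000-point grid and refining with Brent's
method (xtol 1e−10); an everywhere-zero displacement (the identity map of
pure uniparental reproduction) or no upward sign change returns "no
threshold". Note a symmetry worth knowing: when *both* cytotypes self with
the same capacity the map is invariant under `f4 → 1−f4` and the threshold
is pinned at 0.5 no matter how strong selfing is; selfing lowers the
threshold only when it asymmetrically benefits the polyploid (e.g.
`self_compatible: {2x: false, 4x: true}`, the self-compatible-polyploid
scenario motivating the model). `iterate_recursion` also reports the
*exclusion horizon*: the first generation at which `f4 < 1/(2·n_adults)`,
the deterministic analogue of loss in a finite population.

## Experiment drivers

* **Trajectory panels** (`run_trajectory_panel`): ensembles across
  outcrossing probabilities sharing the replicate seed stream, so replicate
  i experiences the same fitness deviation in every panel (paired design).
* **Selfing × outcrossing sweep** (`run_selfing_outcrossing_sweep`): per
  cell, triploid fitness and UG production are forced to zero so the sweep
  isolates the pollination interaction.
* **MCE surface** (`run_mce_surface`): grids over triploid fitness, UG rate
  and a *uniparental reproduction* axis. The uniparental axis value `v` is
  mapped to `(a_selfing=1, p_outcross=1−v, c_clonal=0)`: `v` is then exactly
  the realized uniparental fraction of ovules, `v=1` bypasses cross-mating
  entirely and `v=0` is obligate outcrossing. The mapping is an argument and
  can be replaced (e.g. by a clonality mapping `c_clonal=v`). The
  triploid-fitness axis couples `f3_fertility = t3_fitness` by default,
  because triploids relieve MCE chiefly by returning 2n/3n gametes to the
  mating pool — survival without fertility makes triploids a recruitment
  sink that *strengthens* exclusion of the tetraploid. Each cell reports the
  ABM establishment probability, the oracle exclusion horizon, and an "MCE
  strength" `q0 − establishment probability` (positive = exclusion relative
  to the neutral-drift baseline `q0`; negative values are possible and
  meaningful, see below).

Per-cell seeds are derived from `SeedSequence(base_seed, cell-values)`, so
sweep results are invariant to grid ordering and to which other cells are
requested.

A finding the test suite documents quantitatively: the relief mechanisms do
not merely restore neutrality, they can overshoot it. With fertile triploids
(`t3 = f3 = 1`) under outcrossing, mixed matings convert diploid
reproductive output into 3x/4x offspring and the polyploid lineage gains a
systematic frequency advantage (establishment ~1 rather than ~`q0`), and
full selfing combined with UG production converts diploids to tetraploids
at rate `u²` per selfed offspring. "High lever value" is therefore expected
to *exceed* the neutral baseline, not match it, and the corresponding
surface tests assert the neutral-equality reading and are expected to fail
wherever the overshoot mechanisms operate.

## Problem sizes and numerical choices

Reference study conditions: `n_adults = 500`, `q0 = 0.05`, `B = 10`,
`n_generations = 200`, 100 replicates, `sigma_fitness = 2.5` for trajectory
designs and 0 for mechanism-isolation designs. The neutral-baseline and
surface designs use `n_adults = 100`: neutral drift from 5% needs of order
2N generations to absorb, so at N = 500 a 200-generation horizon censors
most would-be fixations and the comparison against the theoretical fixation
probability `q0` would be meaningless; at N = 100 absorption completes
within the horizon. Monotonicity checks use 500 replicates per cell at
N = 500 with one-sided Fisher exact tests (α = 0.01) between adjacent
cells, so only statistically significant ordering violations count.

Founder counts round half-up on `q0·n_adults`. Probability-mass invariants
are enforced to 1e−12. Under pure outcrossing the deterministic `f4`
sequence squares each generation and underflows to exactly 0 after ~8 steps
from 0.05; consumers should treat 0 as the absorbed state. Output tables are
TSV with floats at 17 significant digits; `experiments.read_table` reads
them back bit-exactly (`float_precision="round_trip"`).

## What the generator does and does not emulate

The simulator covers the mating-system mechanics of MCE: triploid block and
fertility, unreduced gametes, selfing timing against pollinator activity,
clonality via genet tracking, assortative donor weighting, per-event fitness
lotteries, and drift at constant census size. It does **not** model spatial
structure or pollinator foraging behavior, pollen quantity/competition on
stigmas, inbreeding depression in selfed offspring, seed banks, overlapping
generations or demographic growth, or the two-species genetics of
allopolyploids. Passing tests therefore speak to the frequency-dependent
mating dynamics, not to spatially or demographically explicit predictions;
parameters like `p_outcross` compress the entire pollinator environment
into a single per-ovule probability.

## Known limitations

* Triploid gamete behavior is phenomenological (`f3_fertility` +
  `g3_spectrum`); real triploid meiosis produces aneuploid spectra that vary
  by taxon.
* The fitness deviation is a single additive fecundity offset; it does not
  age, segregate, or respond to environment.
* Cytotypes above 4x are inviable by construction; the model cannot address
  hexaploid formation.
* The establishment threshold (0.5) is a reporting convention for runs that
  do not absorb; sensitivity to it can be probed via `establish_threshold`.
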