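"""Per-ovule mating mechanics: gametes, ovule fates, pollen donors, zygotes.

These mechanics are what generates minority cytotype exclusion: a rare
tetraploid mother mostly receives haploid pollen from the diploid majority,
so her outcrossed ovules become triploid zygotes whose survival is scaled by
``t3_fitness`` (0 = complete triploid block).  Autonomous selfing, clonality,
unreduced gametes, fertile triploids and assortative pollen transfer are the
five levers that can break this frequency dependence.

The scalar operations (:func:`resolve_ovule_fate`, :func:`draw_pollen_donor`,
:func:`form_zygote`, :func:`zygote_viability`) define the model one ovule at
a time; :func:`produce_offspring_pool` applies exactly the same rules to all
ovules of a generation in vectorized form.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

from .params import DIPLOID, TETRAPLOID, TRIPLOID, Population, SimParams, TimingMode

__all__ = [
    "GameteDistribution",
    "OvuleFate",
    "Origin",
    "OffspringPool",
    "FateProbs",
    "fate_probabilities",
    "gamete_distribution",
    "gamete_prob_matrix",
    "resolve_ovule_fate",
    "draw_pollen_donor",
    "form_zygote",
    "zygote_viability",
    "viability_by_ploidy",
    "produce_offspring_pool",
]

#: gamete classes are indexed 0..4 where 0 is a non-functional gamete and
#: k>=1 is a gamete carrying k genome copies (1n..4n)
NONFUNCTIONAL = 0
N_GAMETE_CLASSES = 5

_CYT_CODE = {DIPLOID: 0, TRIPLOID: 1, TETRAPLOID: 2}


class OvuleFate(str, Enum):
    outcrossed = "outcrossed"
    selfed = "selfed"
    unfertilized = "unfertilized"


class Origin(str, Enum):
    """How an offspring individual was produced."""

    clonal = "clonal"
    outcross = "sexual-outcross"
    selfed = "sexual-self"
    geitonogamous = "sexual-geitonogamous"


class FateProbs(NamedTuple):
    outcrossed: float
    selfed: float
    unfertilized: float


@dataclass(frozen=True)
class GameteDistribution:
    """Probability mass over gamete classes {nonfunctional, 1n, 2n, 3n, 4n}."""

    probs: np.ndarray  # length 5, index = genome copies (0 = nonfunctional)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_GAMETE_CLASSES,):
            raise ValueError("GameteDistribution needs 5 class masses")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("gamete class masses must be non-negative and sum to 1")
        object.__setattr__(self, "probs", p)

    def mass(self, label: str) -> float:
        idx = {"nonfunctional": 0, "1n": 1, "2n": 2, "3n": 3, "4n": 4}[label]
        return float(self.probs[idx])


def gamete_prob_matrix(params: SimParams) -> np.ndarray:
    """(3, 5) matrix of gamete-class probabilities, rows = cytotype (2x, 3x, 4x).

    Euploid parents produce reduced gametes at rate 1-u and unreduced gametes
    at rate u (a 2n gamete from a diploid, a 4n gamete from a tetraploid).
    Triploid gametes are functional with probability ``f3_fertility`` and then
    follow the configured 1n/2n/3n spectrum; the remaining mass is
    non-functional (aneuploid) and fertilizes nothing.
    """
    u = params.u_ug
    g3 = params.g3_array() * params.f3_fertility
    mat = np.zeros((3, N_GAMETE_CLASSES))
    mat[0, 1] = 1.0 - u  # 2x -> 1n
    mat[0, 2] = u        # 2x -> 2n (unreduced)
    mat[1, 0] = 1.0 - params.f3_fertility
    mat[1, 1:4] = g3
    mat[2, 2] = 1.0 - u  # 4x -> 2n
    mat[2, 4] = u        # 4x -> 4n (unreduced)
    return mat


def gamete_distribution(cytotype: int, params: SimParams) -> GameteDistribution:
    """Gamete-class distribution for one parental cytotype."""
    if cytotype not in _CYT_CODE:
        raise ValueError(f"unknown cytotype {cytotype!r}; expected one of 2, 3, 4")
    return GameteDistribution(gamete_prob_matrix(params)[_CYT_CODE[cytotype]])


def fate_probabilities(
    timing_mode: TimingMode, a_selfing: float, p_outcross: float
) -> FateProbs:
    """Closed-form ovule-fate probabilities under each selfing-timing mode.

    delayed:   outcross pollen claims the ovule first (prob p); autonomous
               selfing rescues a fraction a of the remainder.
    prior:     autonomous selfing claims the ovule first (prob a); outcross
               pollen fertilizes a fraction p of the remainder.
    competing: each ovule experiences one of the two orderings with
               probability 1/2 (marginally, the average of the two).
    """
    a, p = a_selfing, p_outcross
    if timing_mode == TimingMode.delayed:
        return FateProbs(p, (1 - p) * a, (1 - p) * (1 - a))
    if timing_mode == TimingMode.prior:
        return FateProbs((1 - a) * p, a, (1 - a) * (1 - p))
    if timing_mode == TimingMode.competing:
        d = fate_probabilities(TimingMode.delayed, a, p)
        r = fate_probabilities(TimingMode.prior, a, p)
        return FateProbs(*(0.5 * (x + y) for x, y in zip(d, r)))
    raise ValueError(f"unknown timing mode {timing_mode!r}")


def resolve_ovule_fate(
    timing_mode: TimingMode,
    a_selfing: float,
    p_outcross: float,
    rng: np.random.Generator,
) -> OvuleFate:
    """Draw the fate of a single ovule (donor, if any, is attached later)."""
    probs = fate_probabilities(timing_mode, a_selfing, p_outcross)
    r = rng.random()
    if r < probs.outcrossed:
        return OvuleFate.outcrossed
    if r < probs.outcrossed + probs.selfed:
        return OvuleFate.selfed
    return OvuleFate.unfertilized


def draw_pollen_donor(
    population: Population,
    mother_index: int,
    alpha_assort: float,
    rng: np.random.Generator,
) -> int:
    """Sample the index of the outcross-pollen donor for one ovule.

    Donors of the mother's own cytotype carry weight (1 + alpha_assort),
    all others weight 1 (alpha = 0 is random mating).  The mother herself is
    in the donor pool — a self-draw is autogamous selfing — and ramets of her
    genet are eligible, which is what makes geitonogamy possible.
    """
    if population.n == 0:
        raise ValueError("cannot draw a pollen donor from an empty population")
    same = population.cytotype == population.cytotype[mother_index]
    weights = np.where(same, 1.0 + alpha_assort, 1.0)
    return int(rng.choice(population.n, p=weights / weights.sum()))


def form_zygote(maternal_gamete: int, paternal_gamete: int) -> int:
    """Zygote ploidy as the sum of the two gametes' genome-copy numbers."""
    if maternal_gamete <= 0 or paternal_gamete <= 0:
        raise ValueError("cannot form a zygote from a non-functional gamete")
    return maternal_gamete + paternal_gamete


def viability_by_ploidy(params: SimParams) -> np.ndarray:
    """Survival weight per zygote ploidy 0..8 (euploid 1, triploid t3, rest 0)."""
    v = np.zeros(9)
    if 2 <= params.max_ploidy_viable:
        v[2] = 1.0
    if 3 <= params.max_ploidy_viable:
        v[3] = params.t3_fitness
    if 4 <= params.max_ploidy_viable:
        v[4] = 1.0
    return v


def zygote_viability(
    ploidy: int,
    origin: Origin,
    mother_cytotype: int,
    donor_genet: int,
    mother_genet: int,
    params: SimParams,
) -> float:
    """Zygote-to-recruit survival weight in [0, 1].

    Euploid zygotes (2x, 4x) survive with weight 1, triploids with weight
    ``t3_fitness``, anything above ``max_ploidy_viable`` dies.  Selfed and
    geitonogamous zygotes (donor genet equals mother genet) are additionally
    zeroed when the maternal cytotype is not self-compatible.
    """
    if ploidy < 2:
        raise ValueError("zygote ploidy must be at least 2")
    w = viability_by_ploidy(params)[ploidy] if ploidy <= 8 else 0.0
    is_uniparental = origin in (Origin.selfed, Origin.geitonogamous) or (
        donor_genet == mother_genet
    )
    if is_uniparental and origin != Origin.clonal and not params.sc_flag(mother_cytotype):
        w = 0.0
    return float(w)


@dataclass
class OffspringPool:
    """Viable offspring of one generation, before recruitment.

    Zero-weight offspring have already been dropped; ``weight`` is the
    zygote-to-recruit survival weight used by proportional recruitment.
    """

    cytotype: np.ndarray
    genet_id: np.ndarray
    weight: np.ndarray
    origin: np.ndarray  # array of Origin values (object dtype)
    next_genet_id: int

    @property
    def size(self) -> int:
        return int(self.cytotype.size)


def _draw_gametes(
    cyt_codes: np.ndarray, gam_cdf: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized categorical gamete draw; returns genome copies (0 = nonfunctional)."""
    r = rng.random(cyt_codes.size)
    rows = gam_cdf[cyt_codes]  # (n, 5) cumulative probs
    return (r[:, None] > rows).sum(axis=1).astype(np.int8)


def produce_offspring_pool(
    population: Population, params: SimParams, rng: np.random.Generator
) -> OffspringPool:
    """Generate the full viable offspring pool of one generation.

    Each adult allocates its fecundity F between clonal propagules
    (mean c*F) and sexual ovules (mean (1-c)*F), with Poisson-realized
    counts; for tetraploid adults F = max(0, fecundity_b + delta) where delta
    is the replicate's polyploidization fitness deviation.  Every sexual
    ovule independently passes through fate resolution, donor sampling,
    gamete draws, zygote formation and viability weighting; ovules that are
    unfertilized, receive a non-functional gamete, or produce a zero-weight
    zygote are dropped.  An empty pool signals global reproductive failure.
    """
    n = population.n
    cyt = population.cytotype
    cyt_codes = (cyt - 2).astype(np.intp)

    fec = np.full(n, params.fecundity_b)
    if params.sigma_fitness > 0 or population.fitness_deviation != 0.0:
        fec[cyt == TETRAPLOID] = max(0.0, params.fecundity_b + population.fitness_deviation)

    n_clonal = rng.poisson(params.c_clonal * fec)
    n_ovules = rng.poisson((1.0 - params.c_clonal) * fec)

    # --- clonal propagules: copy cytotype and genet id ---------------------
    clone_parents = np.repeat(np.arange(n), n_clonal)
    clone_cyt = cyt[clone_parents]
    clone_w = np.where(clone_cyt == TRIPLOID, params.t3_fitness, 1.0)
    keep = clone_w > 0
    clone_cyt, clone_w = clone_cyt[keep], clone_w[keep]
    clone_genet = population.genet_id[clone_parents][keep]
    clone_origin = np.empty(clone_cyt.size, dtype=object)
    clone_origin[:] = Origin.clonal

    # --- sexual ovules ------------------------------------------------------
    mothers = np.repeat(np.arange(n), n_ovules)
    m = mothers.size
    probs = fate_probabilities(params.timing_mode, params.a_selfing, params.p_outcross)
    r = rng.random(m)
    is_out = r < probs.outcrossed
    is_self = (~is_out) & (r < probs.outcrossed + probs.selfed)
    mothers = mothers[is_out | is_self]
    fert_out = is_out[is_out | is_self]  # True = outcrossed, False = autonomous selfing

    # pollen donors for outcrossed ovules: weight (1 + alpha) for the mother's
    # cytotype, 1 otherwise; the mother and her ramets are in the pool
    donors = mothers.copy()  # selfed ovules: donor is the mother herself
    out_idx = np.flatnonzero(fert_out)
    if out_idx.size:
        counts = np.array([(cyt_codes == k).sum() for k in range(3)], dtype=float)
        members = [np.flatnonzero(cyt_codes == k) for k in range(3)]
        mother_codes = cyt_codes[mothers[out_idx]]
        wmat = np.ones((3, 3)) + params.alpha_assort * np.eye(3)
        class_probs = wmat * counts[None, :]
        class_probs /= class_probs.sum(axis=1, keepdims=True)
        cdf = np.cumsum(class_probs, axis=1)
        rc = rng.random(out_idx.size)
        donor_class = (rc[:, None] > cdf[mother_codes]).sum(axis=1)
        donor_local = np.empty(out_idx.size, dtype=np.int64)
        for k in range(3):
            sel = donor_class == k
            if sel.any():
                donor_local[sel] = members[k][rng.integers(0, int(counts[k]), sel.sum())]
        donors[out_idx] = donor_local

    maternal_gam = _draw_gametes(
        cyt_codes[mothers], np.cumsum(gamete_prob_matrix(params), axis=1), rng
    )
    paternal_gam = _draw_gametes(
        cyt_codes[donors], np.cumsum(gamete_prob_matrix(params), axis=1), rng
    )

    functional = (maternal_gam > 0) & (paternal_gam > 0)
    ploidy = (maternal_gam + paternal_gam).astype(np.intp)
    viab = viability_by_ploidy(params)
    w = np.where(functional, viab[np.minimum(ploidy, 8)], 0.0)

    # self-incompatibility: selfed ovules and outcrossed ovules whose donor is
    # a ramet of the mother's genet (geitonogamy) are uniparental
    same_genet = population.genet_id[donors] == population.genet_id[mothers]
    uniparental = (~fert_out) | same_genet
    sc = np.array([params.sc_flag(c) for c in (DIPLOID, TRIPLOID, TETRAPLOID)])
    w = np.where(uniparental & ~sc[cyt_codes[mothers]], 0.0, w)

    keep = w > 0
    sex_cyt = ploidy[keep].astype(np.int8)
    sex_w = w[keep]
    fk = fert_out[keep]
    self_draw = donors[keep] == mothers[keep]  # implies same genet
    sg = same_genet[keep]
    origin = np.empty(sex_cyt.size, dtype=object)
    origin[~fk | (fk & self_draw)] = Origin.selfed
    origin[fk & sg & ~self_draw] = Origin.geitonogamous
    origin[fk & ~sg] = Origin.outcross
    sex_genet = population.next_genet_id + np.arange(sex_cyt.size, dtype=np.int64)

    return OffspringPool(
        cytotype=np.concatenate([clone_cyt, sex_cyt]),
        genet_id=np.concatenate([clone_genet, sex_genet]),
        weight=np.concatenate([clone_w, sex_w]),
        origin=np.concatenate([clone_origin, origin]),
        next_genet_id=int(population.next_genet_id + sex_cyt.size),
    )
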