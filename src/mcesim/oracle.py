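"""Infinite-population (mean-field) cytotype recursion.

Exact one-generation expectation of the agent-based model, obtained by
enumerating every discrete outcome path — maternal cytotype, ovule fate,
donor cytotype, maternal gamete, paternal gamete, zygote viability — with
its probability, plus the clonal mass.  Used to validate the stochastic
engine and to compute deterministic exclusion horizons and the unstable
frequency threshold that defines minority cytotype exclusion.

By construction the oracle ignores the per-replicate fitness deviation
(sigma) and all finite-size sampling.  Geitonogamy is indistinguishable from
autogamy at mean field (any one genet has measure zero), so the donor
distribution excludes the mother as an individual and uniparental
reproduction enters only through the selfed fate and clonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .mating import fate_probabilities, gamete_prob_matrix, viability_by_ploidy
from .params import SimParams

__all__ = [
    "FrequencyState",
    "GlobalReproductiveFailure",
    "expected_offspring_distribution",
    "iterate_recursion",
    "unstable_threshold",
]


class GlobalReproductiveFailure(RuntimeError):
    """Total viable offspring mass is zero: the population cannot reproduce."""


@dataclass(frozen=True)
class FrequencyState:
    """Cytotype frequencies (f2, f3, f4) on the simplex."""

    f2: float
    f3: float
    f4: float

    def __post_init__(self):
        v = np.array([self.f2, self.f3, self.f4])
        if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must be a probability vector, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f2, self.f3, self.f4])

    @classmethod
    def from_array(cls, v: np.ndarray) -> "FrequencyState":
        return cls(float(v[0]), float(v[1]), float(v[2]))

    @classmethod
    def from_q(cls, q: float) -> "FrequencyState":
        """Diploid/tetraploid state with tetraploid frequency q (no triploids)."""
        return cls(1.0 - q, 0.0, q)


def expected_offspring_distribution(
    state: FrequencyState, params: SimParams
) -> FrequencyState:
    """Exact next-generation cytotype frequencies in an infinite population.

    Each cytotype m at frequency f_m contributes clonal mass c*B*f_m (times
    the triploid survival weight for 3x ramets) and sexual mass (1-c)*B*f_m
    split over ovule fates.  Outcrossed ovules draw the paternal gamete from
    the assortment-weighted population pollen pool; selfed ovules draw both
    gametes from the mother's own distribution, gated by self-compatibility.
    Raises :class:`GlobalReproductiveFailure` if no viable mass remains.
    """
    f = state.as_array()
    gam = gamete_prob_matrix(params)  # (3 cytotypes, 5 gamete classes)
    viab = viability_by_ploidy(params)
    fate = fate_probabilities(params.timing_mode, params.a_selfing, params.p_outcross)
    b, c = params.fecundity_b, params.c_clonal
    sc = np.array([params.sc_flag(k) for k in (2, 3, 4)], dtype=float)
    clone_w = np.array([1.0, params.t3_fitness, 1.0])

    mass = np.zeros(3)  # offspring classes 2x, 3x, 4x
    for mi in range(3):
        fm = f[mi]
        if fm == 0.0:
            continue
        mass[mi] += c * b * fm * clone_w[mi]
        s = (1.0 - c) * b * fm
        if s == 0.0:
            continue
        # assortment-weighted donor cytotype probabilities (mother excluded
        # as an individual: measure zero at infinite size)
        w = 1.0 + params.alpha_assort * (np.arange(3) == mi)
        dw = w * f
        donor_p = dw / dw.sum()
        pollen = donor_p @ gam  # population pollen-pool gamete distribution
        g_m = gam[mi]
        # functional gamete classes are 1n..4n (index 1..4)
        out_paths = np.outer(g_m[1:], pollen[1:])
        self_paths = np.outer(g_m[1:], g_m[1:]) * sc[mi]
        for i in range(4):
            for j in range(4):
                pl = (i + 1) + (j + 1)
                v = viab[pl] if pl <= 8 else 0.0
                if v == 0.0 or pl > 4:
                    continue
                contrib = s * v * (
                    fate.outcrossed * out_paths[i, j] + fate.selfed * self_paths[i, j]
                )
                mass[pl - 2] += contrib

    total = mass.sum()
    if total <= 0.0:
        raise GlobalReproductiveFailure(
            "expected viable offspring mass is zero for this state and parameter set"
        )
    return FrequencyState.from_array(mass / total)


def iterate_recursion(
    state0: FrequencyState, params: SimParams, n_steps: int
) -> tuple[list[FrequencyState], int | None]:
    """Apply the recursion ``n_steps`` times.

    Returns the state sequence (length n_steps + 1) and the exclusion
    horizon: the first step at which f4 falls below 1/(2*n_adults) — the
    deterministic analogue of loss in a population of n_adults — or None if
    it never does.
    """
    states = [state0]
    threshold = 1.0 / (2.0 * params.n_adults)
    horizon = 0 if state0.f4 < threshold else None
    for t in range(1, n_steps + 1):
        states.append(expected_offspring_distribution(states[-1], params))
        if horizon is None and states[-1].f4 < threshold:
            horizon = t
    return states, horizon


def _f4_map(q: float, params: SimParams) -> float:
    return expected_offspring_distribution(FrequencyState.from_q(q), params).f4


def unstable_threshold(
    params: SimParams, grid_size: int = 1000, tol: float = 1e-10
) -> float | None:
    """Interior unstable fixed point of the tetraploid-frequency map.

    Below this frequency the deterministic dynamics exclude the tetraploid;
    above it, the tetraploid excludes the diploid.  Located by bracketing a
    sign change of g(q) = f4' - q (from negative to positive, the unstable
    crossing) on a grid and refining by bisection.  Returns None when the
    map has no interior unstable root — MCE absent (e.g. the identity map of
    pure autonomous selfing).
    """
    qs = np.linspace(1e-6, 1.0 - 1e-6, grid_size)
    g = np.array([_f4_map(q, params) - q for q in qs])
    if np.max(np.abs(g)) < 1e-12:
        return None  # identity map: every frequency is (neutrally) fixed
    for i in range(grid_size - 1):
        if g[i] == 0.0 and 0 < i < grid_size - 1 and g[i - 1] < 0 < g[i + 1]:
            return float(qs[i])
        if g[i] < 0.0 < g[i + 1]:
            root = brentq(
                lambda q: _f4_map(q, params) - q, qs[i], qs[i + 1], xtol=tol
            )
            return float(root)
    return None
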