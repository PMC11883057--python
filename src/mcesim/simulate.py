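"""Discrete-generation dynamics, outcome classification, replicate ensembles.

A replicate advances a constant-size adult population through non-overlapping
generations (offspring-pool production followed by weight-proportional
recruitment of exactly ``n_adults`` recruits, Wright-Fisher style) until the
polyploid lineage is lost, the tetraploid fixes, or ``n_generations`` is
reached.  Ensembles aggregate establishment probability and mean trajectories
over independently seeded replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mating import OffspringPool, produce_offspring_pool
from .params import Population, SimParams, init_population

__all__ = [
    "TerminalState",
    "ReplicateResult",
    "EnsembleResult",
    "recruit",
    "step_generation",
    "run_replicate",
    "run_ensemble",
    "trajectory_frame",
]


class TerminalState:
    established = "established"
    excluded = "excluded"
    persisting = "persisting"
    global_extinction = "global_extinction"


def recruit(
    pool: OffspringPool, params: SimParams, rng: np.random.Generator
) -> Population | None:
    """Sample the next adult cohort from the offspring pool.

    Exactly ``n_adults`` recruits are drawn with probability proportional to
    recruit weight (multinomial, i.e. with replacement), so the expected
    cytotype composition of the next generation equals the weighted pool
    composition regardless of pool size.  An empty pool returns None: global
    reproductive failure.
    """
    if pool.size == 0:
        return None
    p = pool.weight / pool.weight.sum()
    idx = rng.choice(pool.size, size=params.n_adults, replace=True, p=p)
    return Population(
        cytotype=pool.cytotype[idx].copy(),
        genet_id=pool.genet_id[idx].copy(),
        fitness_deviation=0.0,  # caller re-attaches the replicate deviation
        generation_index=0,
        next_genet_id=pool.next_genet_id,
    )


def step_generation(
    population: Population, params: SimParams, rng: np.random.Generator
) -> Population | None:
    """Advance one generation; None signals global extinction."""
    pool = produce_offspring_pool(population, params, rng)
    nxt = recruit(pool, params, rng)
    if nxt is None:
        return None
    nxt.fitness_deviation = population.fitness_deviation
    nxt.generation_index = population.generation_index + 1
    return nxt


@dataclass
class ReplicateResult:
    """One run: the cytotype-frequency trajectory and its terminal outcome.

    ``trajectory`` has shape (generations_run + 1, 3) with columns
    (freq_2x, freq_3x, freq_4x); row 0 is the founding generation.
    """

    trajectory: np.ndarray
    terminal_state: str
    generations_run: int
    fitness_deviation: float
    seed: int

    @property
    def final_frequencies(self) -> np.ndarray:
        return self.trajectory[-1]

    def polyploid_frequency(self, include_3x: bool = False) -> np.ndarray:
        f = self.trajectory
        return f[:, 2] + (f[:, 1] if include_3x else 0.0)


def _classify(freqs: np.ndarray, params: SimParams) -> str:
    f2, f3, f4 = freqs
    if f3 + f4 == 0.0:
        return TerminalState.excluded
    poly = f4 + (f3 if params.polyploid_includes_3x else 0.0)
    if f4 == 1.0 or poly >= params.establish_threshold:
        return TerminalState.established
    return TerminalState.persisting


def run_replicate(params: SimParams, replicate_index: int) -> ReplicateResult:
    """Run one seeded replicate to absorption or ``n_generations``.

    The replicate owns a single pseudorandom stream seeded
    ``base_seed + replicate_index``; identical (params, index) pairs give
    bit-identical trajectories.  Absorption is declared when the polyploid
    lineage (3x + 4x) is extinct — terminal only when unreduced gametes
    cannot regenerate it (u_ug = 0) — or when the tetraploid is fixed.
    """
    seed = params.base_seed + replicate_index
    rng = np.random.default_rng(seed)
    pop = init_population(params, rng)
    traj = [pop.frequencies()]
    terminal: str | None = None

    f2, f3, f4 = traj[0]
    if f3 + f4 == 0.0 and params.u_ug == 0.0:
        terminal = TerminalState.excluded
    elif f4 == 1.0:
        terminal = TerminalState.established

    while terminal is None and pop.generation_index < params.n_generations:
        nxt = step_generation(pop, params, rng)
        if nxt is None:
            terminal = TerminalState.global_extinction
            break
        pop = nxt
        f = pop.frequencies()
        traj.append(f)
        f2, f3, f4 = f
        if f3 + f4 == 0.0 and params.u_ug == 0.0:
            terminal = TerminalState.excluded
        elif f2 == 0.0 and f3 == 0.0:
            terminal = TerminalState.established

    trajectory = np.asarray(traj)
    if terminal is None:
        terminal = _classify(trajectory[-1], params)
    return ReplicateResult(
        trajectory=trajectory,
        terminal_state=terminal,
        generations_run=trajectory.shape[0] - 1,
        fitness_deviation=pop.fitness_deviation,
        seed=seed,
    )


@dataclass
class EnsembleResult:
    """Aggregate of independently seeded replicates.

    ``mean_trajectory`` extends each replicate at its last (absorbing) state
    out to ``n_generations`` before averaging, so the ensemble mean is defined
    at every generation.
    """

    replicates: list[ReplicateResult]
    establishment_probability: float
    establishment_se: float
    mean_trajectory: np.ndarray
    params: SimParams

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def _padded(traj: np.ndarray, length: int) -> np.ndarray:
    if traj.shape[0] >= length:
        return traj[:length]
    pad = np.repeat(traj[-1][None, :], length - traj.shape[0], axis=0)
    return np.vstack([traj, pad])


def run_ensemble(params: SimParams, progress: bool = False) -> EnsembleResult:
    """Run ``n_replicates`` independent replicates and aggregate them."""
    indices: Sequence[int] = range(params.n_replicates)
    if progress:
        from tqdm import tqdm

        indices = tqdm(indices, desc="replicates")
    replicates = [run_replicate(params, i) for i in indices]
    n_est = sum(r.terminal_state == TerminalState.established for r in replicates)
    p_est = n_est / params.n_replicates
    se = float(np.sqrt(p_est * (1.0 - p_est) / params.n_replicates))
    length = params.n_generations + 1
    mean_traj = np.mean([_padded(r.trajectory, length) for r in replicates], axis=0)
    return EnsembleResult(
        replicates=replicates,
        establishment_probability=p_est,
        establishment_se=se,
        mean_trajectory=mean_traj,
        params=params,
    )


def trajectory_frame(ensemble: EnsembleResult) -> pd.DataFrame:
    """Tidy trajectory table: one row per (replicate, generation)."""
    rows = []
    for i, rep in enumerate(ensemble.replicates):
        g = np.arange(rep.trajectory.shape[0])
        rows.append(
            pd.DataFrame(
                {
                    "replicate": i,
                    "generation": g,
                    "freq_2x": rep.trajectory[:, 0],
                    "freq_3x": rep.trajectory[:, 1],
                    "freq_4x": rep.trajectory[:, 2],
                    "terminal_state": rep.terminal_state,
                    "seed": rep.seed,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
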