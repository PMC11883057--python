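"""Preset experiment drivers: trajectory panels and establishment sweeps.

Three designs are provided:

* :func:`run_trajectory_panel` — replicate trajectory ensembles at a set of
  outcrossing probabilities with autonomous selfing fixed (the classic
  low-vs-high pollinator-effectiveness comparison);
* :func:`run_selfing_outcrossing_sweep` — establishment probability over the
  (autonomous selfing capacity x outcrossing probability) grid with the
  triploid pathway and unreduced gametes switched off;
* :func:`run_mce_surface` — establishment probability and deterministic
  exclusion horizon over (triploid fitness x unreduced-gamete rate x
  uniparental-reproduction) grids, quantifying when uniparental reproduction
  still matters for establishment.

Every driver derives per-cell seeds deterministically from the scenario base
seed and the cell's grid coordinates, so results are invariant to evaluation
order and reproducible from the run manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .oracle import FrequencyState, GlobalReproductiveFailure, iterate_recursion
from .simulate import EnsembleResult, run_ensemble
from .params import SimParams

__all__ = [
    "SweepResult",
    "run_selfing_outcrossing_sweep",
    "run_trajectory_panel",
    "run_mce_surface",
    "default_uniparental_mapping",
    "cell_seed",
    "make_manifest",
    "write_table",
    "write_manifest",
]


def cell_seed(base_seed: int, *coords: float) -> int:
    """Deterministic per-cell base seed (< 2**31) keyed on the cell's values.

    Keyed on parameter values rather than grid indices, so a cell's seed —
    and hence its result — is invariant to grid ordering and to which other
    cells are present.
    """
    key = np.asarray(coords, dtype=np.float64).tobytes()
    words = tuple(int(w) for w in np.frombuffer(key, dtype=np.uint32))
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=words)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class SweepResult:
    """Grid of establishment probabilities with Monte-Carlo uncertainty.

    ``table`` holds one record per grid cell; ``outcomes`` maps each cell's
    row index to the list of per-replicate terminal states, so every summary
    can be recomputed from the stored outcomes.
    """

    table: pd.DataFrame
    outcomes: dict[int, list[str]]


def _summarize_cell(ens: EnsembleResult) -> dict:
    finals = np.array([r.final_frequencies[2] for r in ens.replicates])
    return {
        "establishment_prob": ens.establishment_probability,
        "establishment_se": ens.establishment_se,
        "n_replicates": ens.n_replicates,
        "mean_final_f4": float(finals.mean()),
        "base_seed": ens.params.base_seed,
    }


def run_selfing_outcrossing_sweep(
    params: SimParams,
    a_grid: Sequence[float],
    p_grid: Sequence[float],
    progress: bool = False,
) -> SweepResult:
    """Establishment probability over the selfing x outcrossing grid.

    Triploid fitness and the unreduced-gamete rate are forced to 0 in every
    cell so the sweep isolates the interaction between pollen vectors and
    self-pollination.
    """
    rows, outcomes = [], {}
    cells = [(i, j, a, p) for i, a in enumerate(a_grid) for j, p in enumerate(p_grid)]
    iterator: Iterable = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="sweep cells")
    for i, j, a, p in iterator:
        cp = params.replace(
            a_selfing=float(a),
            p_outcross=float(p),
            t3_fitness=0.0,
            u_ug=0.0,
            base_seed=cell_seed(params.base_seed, a, p),
        )
        ens = run_ensemble(cp)
        row = {"a_selfing": float(a), "p_outcross": float(p), **_summarize_cell(ens)}
        outcomes[len(rows)] = [r.terminal_state for r in ens.replicates]
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), outcomes=outcomes)


def run_trajectory_panel(
    params: SimParams, p_values: Sequence[float], progress: bool = False
) -> dict[float, EnsembleResult]:
    """One trajectory ensemble per outcrossing probability.

    All panels share the scenario base seed, so replicate i uses the same
    pseudorandom stream — and in particular the same polyploid fitness
    deviation — across p values (a paired design).
    """
    return {
        float(p): run_ensemble(params.replace(p_outcross=float(p)), progress=progress)
        for p in p_values
    }


def default_uniparental_mapping(v: float) -> dict:
    """Map the uniparental-reproduction axis to concrete mating parameters.

    The axis value v is the realized uniparental fraction of ovules: full
    autonomous selfing capacity with the outcross-pollen probability reduced
    to 1 - v (and no clonality), so v = 1 bypasses cross-mating entirely and
    v = 0 is obligate outcrossing.
    """
    return {"a_selfing": 1.0, "p_outcross": 1.0 - float(v), "c_clonal": 0.0}


def run_mce_surface(
    params: SimParams,
    t3_grid: Sequence[float],
    u_grid: Sequence[float],
    uniparental_grid: Sequence[float],
    mapping: Callable[[float], dict] = default_uniparental_mapping,
    couple_triploid_fertility: bool = True,
    progress: bool = False,
) -> SweepResult:
    """Establishment probability surface over the three MCE-relief pathways.

    The triploid-fitness axis by default sets gamete fertility along with
    zygote survival (``f3_fertility = t3_fitness``), because triploids
    weaken MCE chiefly by returning unreduced (2n, 3n) gametes to the mating
    pool.  Each cell also reports the mean-field exclusion horizon and the
    MCE strength q0 - establishment probability (positive = exclusion,
    relative to the neutral-drift baseline q0).
    """
    rows, outcomes = [], {}
    cells = [
        (i, j, k, t3, u, v)
        for i, t3 in enumerate(t3_grid)
        for j, u in enumerate(u_grid)
        for k, v in enumerate(uniparental_grid)
    ]
    iterator: Iterable = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="surface cells")
    for i, j, k, t3, u, v in iterator:
        updates = dict(mapping(v))
        updates.update(
            t3_fitness=float(t3),
            u_ug=float(u),
            base_seed=cell_seed(params.base_seed, t3, u, v),
        )
        if couple_triploid_fertility:
            updates["f3_fertility"] = float(t3)
        cp = params.replace(**updates)
        ens = run_ensemble(cp)
        try:
            _, horizon = iterate_recursion(
                FrequencyState.from_q(cp.q0), cp, cp.n_generations
            )
        except GlobalReproductiveFailure:
            horizon = None
        row = {
            "t3_fitness": float(t3),
            "u_ug": float(u),
            "uniparental": float(v),
            **_summarize_cell(ens),
            "exclusion_horizon": np.nan if horizon is None else horizon,
            "mce_strength": cp.q0 - ens.establishment_probability,
        }
        outcomes[len(rows)] = [r.terminal_state for r in ens.replicates]
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), outcomes=outcomes)


# ---------------------------------------------------------------------------
# provenance and tidy output


def make_manifest(
    scenario: str, params: SimParams, extra: dict | None = None
) -> dict:
    """Run manifest: everything needed to reproduce the output tables."""
    manifest = {
        "scenario": scenario,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "base_seed": params.base_seed,
        "replicate_seeds": [params.base_seed + i for i in range(params.n_replicates)],
        "params": json.loads(params.model_dump_json()),
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with floats at 17 significant digits (lossless round-trip)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` at full float precision."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
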