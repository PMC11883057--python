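"""Model parameters and population state.

All levers of the minority-cytotype-exclusion (MCE) model live in a single
validated :class:`SimParams` object shared by the agent-based simulator and
the deterministic mean-field recursion.  Parameters map one-to-one onto keys
of a flat YAML config file; unknown keys are a hard error so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

__all__ = [
    "TimingMode",
    "SimParams",
    "Population",
    "ConfigError",
    "validate_params",
    "load_config",
    "save_config",
    "init_population",
]

#: integer codes used for cytotypes throughout the package
DIPLOID, TRIPLOID, TETRAPLOID = 2, 3, 4
CYTOTYPES = (DIPLOID, TRIPLOID, TETRAPLOID)


class TimingMode(str, Enum):
    """Order in which outcross pollen deposition and autonomous selfing act on an ovule.

    ``delayed``
        Outcross pollen is deposited first; autonomous selfing can only claim
        ovules left unfertilized (selfing as reproductive assurance).
    ``prior``
        Autonomous selfing acts first; outcross pollen competes only for the
        remaining ovules.
    ``competing``
        Each ovule independently experiences one of the two orderings with
        probability 1/2.
    """

    delayed = "delayed"
    prior = "prior"
    competing = "competing"


class ConfigError(ValueError):
    """Raised for an invalid or malformed parameter set / config file."""


class SimParams(BaseModel):
    """Validated, immutable parameter set for one simulation scenario.

    Defaults follow the reference scenario: a self-compatible tetraploid
    minority arising at 5% frequency in a diploid population of 500 adults,
    with a complete triploid block (``t3_fitness = 0``), no unreduced gametes
    and outcross pollen acting before autonomous selfing.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_adults: int = Field(default=500, ge=1, description="fixed adult population size")
    q0: float = Field(default=0.05, ge=0.0, le=1.0, description="initial tetraploid frequency")
    p_outcross: float = Field(
        default=0.5, ge=0.0, le=1.0,
        description="per-ovule probability that pollinator-borne outcross pollen is deposited",
    )
    a_selfing: float = Field(
        default=0.8, ge=0.0, le=1.0,
        description="autonomous selfing capacity: probability an ovule not claimed by "
        "outcross pollen is self-fertilized",
    )
    timing_mode: TimingMode = TimingMode.delayed
    u_ug: float = Field(
        default=0.0, ge=0.0, le=1.0,
        description="unreduced-gamete rate of euploid (2x, 4x) parents; empirical rates are "
        "c. 1% (median 1.2%)",
    )
    t3_fitness: float = Field(
        default=0.0, ge=0.0, le=1.0,
        description="triploid relative fitness, applied as zygote-to-recruit survival weight "
        "(1 = equal to diploids)",
    )
    f3_fertility: float = Field(
        default=0.0, ge=0.0, le=1.0,
        description="probability that a gamete produced by a triploid is functional",
    )
    g3_spectrum: dict[str, float] = Field(
        default={"1n": 0.25, "2n": 0.375, "3n": 0.375},
        description="ploidy spectrum of functional triploid gametes; default puts 3x the "
        "mass on unreduced (2n+3n) classes relative to reduced 1n gametes",
    )
    c_clonal: float = Field(
        default=0.0, ge=0.0, le=1.0,
        description="allocation to clonal propagules; sexual ovule fecundity scales by (1-c)",
    )
    fecundity_b: float = Field(
        default=10.0, gt=0.0, description="expected ovules per fully sexual adult per generation"
    )
    alpha_assort: float = Field(
        default=0.0, ge=0.0,
        description="extra pollen-donor weight for the mother's own cytotype (0 = random mating)",
    )
    sigma_fitness: float = Field(
        default=0.0, ge=0.0,
        description="SD of the per-replicate polyploid fitness deviation, in ovule-count "
        "units added to fecundity_b",
    )
    self_compatible: dict[str, bool] = Field(
        default={"2x": True, "3x": True, "4x": True},
        description="whether selfed/geitonogamous zygotes of each maternal cytotype are viable",
    )
    max_ploidy_viable: int = Field(
        default=4, ge=2, le=4,
        description="zygotes above this ploidy are inviable; adults above 4x are not modeled",
    )
    n_generations: int = Field(default=200, ge=1)
    establish_threshold: float = Field(
        default=0.5, gt=0.0, le=1.0,
        description="terminal polyploid frequency classifying a run as established when "
        "fixation is not reached",
    )
    polyploid_includes_3x: bool = Field(
        default=False,
        description="whether triploids count toward the tracked polyploid proportion",
    )
    n_replicates: int = Field(default=100, ge=1)
    base_seed: int = Field(default=0, ge=0, description="root of the replicate seed sequence")

    @field_validator("g3_spectrum")
    @classmethod
    def _check_spectrum(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != {"1n", "2n", "3n"}:
            raise ValueError("g3_spectrum must have exactly the keys {'1n','2n','3n'}")
        if any(x < 0 for x in v.values()):
            raise ValueError("g3_spectrum entries must be non-negative")
        if abs(sum(v.values()) - 1.0) > 1e-12:
            raise ValueError(f"g3_spectrum must sum to 1 (got {sum(v.values())!r})")
        return dict(v)

    @field_validator("self_compatible")
    @classmethod
    def _check_sc(cls, v: dict[str, bool]) -> dict[str, bool]:
        if set(v) != {"2x", "3x", "4x"}:
            raise ValueError("self_compatible must have exactly the keys {'2x','3x','4x'}")
        return dict(v)

    # -- convenience accessors -------------------------------------------------

    def g3_array(self) -> np.ndarray:
        """Functional triploid gamete spectrum as probs over ploidy [1n, 2n, 3n]."""
        return np.array([self.g3_spectrum["1n"], self.g3_spectrum["2n"], self.g3_spectrum["3n"]])

    def sc_flag(self, cytotype: int) -> bool:
        return self.self_compatible[f"{cytotype}x"]

    def replace(self, **updates) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        data = self.model_dump(mode="python")
        data.update(updates)
        return validate_params(data)


def validate_params(raw: Mapping | SimParams | None = None, **kwargs) -> SimParams:
    """Build a fully populated :class:`SimParams` from a key-value mapping.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming the
    offending field, before any simulation runs.
    """
    if isinstance(raw, SimParams) and not kwargs:
        return raw
    data = dict(raw or {})
    data.update(kwargs)
    if "timing_mode" in data and isinstance(data["timing_mode"], str):
        try:
            data["timing_mode"] = TimingMode(data["timing_mode"])
        except ValueError as exc:
            raise ConfigError(
                f"timing_mode must be one of {[m.value for m in TimingMode]}"
            ) from exc
    try:
        return SimParams(**data)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid parameters: {msgs}") from exc


def load_config(path: str | Path) -> SimParams:
    """Load a flat YAML config file into a validated :class:`SimParams`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a flat key-value mapping")
    return validate_params(data)


def save_config(params: SimParams, path: str | Path) -> None:
    """Write a :class:`SimParams` as a flat YAML file (round-trips exactly)."""
    data = params.model_dump(mode="python")
    data["timing_mode"] = params.timing_mode.value
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)


# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Adult cohort of one generation.

    ``cytotype`` holds the ploidy (2, 3 or 4) of each adult, ``genet_id`` the
    genetic individual each adult belongs to: founders get unique ids and
    clonal offspring (ramets) inherit their parent's id, so pollen transfer
    between ramets can be recognized as geitonogamous selfing.
    ``fitness_deviation`` is the per-replicate polyploidization fitness effect
    δ ~ N(0, sigma_fitness), added to the tetraploid ovule fecundity.
    """

    cytotype: np.ndarray
    genet_id: np.ndarray
    fitness_deviation: float
    generation_index: int = 0
    next_genet_id: int = field(default=0)

    @property
    def n(self) -> int:
        return int(self.cytotype.size)

    def frequencies(self) -> np.ndarray:
        """Cytotype frequency vector (f2, f3, f4)."""
        n = self.n
        return np.array(
            [
                np.count_nonzero(self.cytotype == DIPLOID) / n,
                np.count_nonzero(self.cytotype == TRIPLOID) / n,
                np.count_nonzero(self.cytotype == TETRAPLOID) / n,
            ]
        )


def init_population(params: SimParams, rng: np.random.Generator) -> Population:
    """Found a population with round(q0 * n_adults) tetraploids, rest diploids.

    The founder tetraploid count is deterministic given (n_adults, q0):
    round-half-up, so a positive q0 never silently yields zero founders when
    q0 * n_adults >= 0.5.  Each founder is its own genet.  The per-replicate
    polyploid fitness deviation is drawn here, as the first use of ``rng``.
    """
    n = params.n_adults
    n4 = int(np.floor(params.q0 * n + 0.5))
    cytotype = np.full(n, DIPLOID, dtype=np.int8)
    cytotype[:n4] = TETRAPLOID
    genet_id = np.arange(n, dtype=np.int64)
    delta = float(rng.normal(0.0, params.sigma_fitness)) if params.sigma_fitness > 0 else 0.0
    return Population(
        cytotype=cytotype,
        genet_id=genet_id,
        fitness_deviation=delta,
        generation_index=0,
        next_genet_id=n,
    )
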