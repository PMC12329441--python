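"""Scenario definition, validation, (de)serialization and grid generators.

A :class:`Scenario` bundles the boundary conditions of one 4-Gyr run: the
onset ages of the two key metabolisms (N2 fixation, oxygenic photosynthesis),
the mantle-phosphorus multiplier, the fungal land-colonization age, solver
controls and a reference :class:`~goebox.params.Params` set.

Ages are given in Ga before present externally; the forward model works in
years elapsed since 4.0 Ga (``t = (4.0 - age) * 1e9``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .params import Params, T_RUN

#: Oxygenic-photosynthesis onset ages (Ga) swept in the metabolic and
#: phosphorus experiments; six visually distinct cases from 3.75 to 2.5 Ga.
OP_ONSETS_GA = (3.75, 3.5, 3.25, 3.0, 2.75, 2.5)

#: Palaeoarchean N2-fixation onset (Ga) used for the middle sweep column
#: (after the earliest oxygenic-photosynthesis onsets).
PALEO_FIX_ON_GA = 3.3


def age_to_time(age_ga: float) -> float:
    """Convert an age in Ga before present to model time in years."""
    return (4.0 - age_ga) * 1.0e9


def time_to_age(t_yr) :
    """Convert model time (years since 4.0 Ga) to age in Ga before present."""
    return 4.0 - np.asarray(t_yr) / 1.0e9


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1.0e-8       # relative tolerance of the stiff integrator
    atol_scale: float = 1.0    # multiplier on the per-species absolute floors
    max_step: float = 5.0e7    # yr
    output_dt: float = 1.0e6   # yr, spacing of the resampled output grid

    def validate(self) -> None:
        if not (self.rtol > 0 and self.atol_scale > 0 and self.max_step > 0
                and self.output_dt > 0):
            raise ValueError("solver settings must be strictly positive")


@dataclass(frozen=True)
class Scenario:
    """Boundary conditions of one simulation.

    ``t_fix_on`` / ``t_op_on`` / ``t_fungi_on`` are ages in Ga before
    present; ``t_fix_on=None`` means biological N2 fixation never evolves.
    """

    id: str
    t_op_on: float
    t_fix_on: Optional[float] = 3.8
    ramp_duration: float = 1.0e8    # yr, logistic expansion of each metabolism
    p_multiplier: float = 1.0       # scales the initial mantle P inventory
    t_fungi_on: float = 0.75        # Ga, fungal weathering boost
    params: Params = field(default_factory=Params)
    solver: SolverSettings = field(default_factory=SolverSettings)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.id:
            raise ValueError("Scenario.id must be a non-empty string")
        if not (0.0 <= self.t_op_on <= 4.0):
            raise ValueError(f"Scenario.t_op_on must lie in [0, 4] Ga, got {self.t_op_on}")
        if self.t_fix_on is not None and not (0.0 <= self.t_fix_on <= 4.0):
            raise ValueError(f"Scenario.t_fix_on must lie in [0, 4] Ga, got {self.t_fix_on}")
        if not (0.0 <= self.t_fungi_on <= 4.0):
            raise ValueError(f"Scenario.t_fungi_on must lie in [0, 4] Ga, got {self.t_fungi_on}")
        if not self.ramp_duration > 0:
            raise ValueError(f"Scenario.ramp_duration must be > 0, got {self.ramp_duration}")
        if not self.p_multiplier > 0:
            raise ValueError(f"Scenario.p_multiplier must be > 0, got {self.p_multiplier}")
        self.params.validate()
        self.solver.validate()

    # -- time conversions --------------------------------------------------
    @property
    def t_op_model(self) -> float:
        return age_to_time(self.t_op_on)

    @property
    def t_fix_model(self) -> Optional[float]:
        return None if self.t_fix_on is None else age_to_time(self.t_fix_on)

    @property
    def t_fungi_model(self) -> float:
        return age_to_time(self.t_fungi_on)

    # -- serialization -----------------------------------------------------
    def to_dict(self, include_params: bool = False) -> dict:
        d = {
            "id": self.id,
            "t_op_on": self.t_op_on,
            "t_fix_on": self.t_fix_on,
            "ramp_duration": self.ramp_duration,
            "p_multiplier": self.p_multiplier,
            "t_fungi_on": self.t_fungi_on,
            "solver": dataclasses.asdict(self.solver),
            "seed": self.seed,
        }
        if include_params:
            d["params"] = self.params.to_dict()
        return d

    def replace(self, **kwargs) -> "Scenario":
        return dataclasses.replace(self, **kwargs)


_SCENARIO_KEYS = {"id", "t_op_on", "t_fix_on", "ramp_duration", "p_multiplier",
                  "t_fungi_on", "solver", "seed", "params"}


def scenario_from_dict(d: dict) -> Scenario:
    unknown = set(d) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "id" not in d or "t_op_on" not in d:
        raise ValueError("scenario config requires at least 'id' and 't_op_on'")
    kw = dict(d)
    if "solver" in kw and isinstance(kw["solver"], dict):
        kw["solver"] = SolverSettings(**kw["solver"])
    if "params" in kw and isinstance(kw["params"], dict):
        kw["params"] = Params.from_dict(kw["params"])
    return Scenario(**kw)


def load_scenario(path) -> Scenario:
    """Read and validate a scenario from a YAML config file.

    Missing fields take their documented defaults; unknown keys are
    rejected; invariant violations raise ``ValueError`` naming the field.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"scenario config {path!r} did not parse to a mapping")
    return scenario_from_dict(data)


def save_scenario(scenario: Scenario, path, include_params: bool = False) -> None:
    """Write a scenario config; ``load_scenario(save_scenario(s)) == s``."""
    with open(path, "w") as fh:
        fh.write("# goebox scenario (ages in Ga before present, durations in yr)\n")
        yaml.safe_dump(scenario.to_dict(include_params=include_params), fh, sort_keys=True)


# -- generators ------------------------------------------------------------

def nominal_scenario(params: Optional[Params] = None, **overrides) -> Scenario:
    """The reference chronology: N2 fixation at 3.8 Ga, oxygenic
    photosynthesis at 3.5 Ga, 100-Myr metabolic ramps, nominal P growth."""
    kw = dict(id="nominal", t_fix_on=3.8, t_op_on=3.5,
              ramp_duration=1.0e8, p_multiplier=1.0)
    if params is not None:
        kw["params"] = params
    kw.update(overrides)
    return Scenario(**kw)


def fig2_grid(params: Optional[Params] = None,
              op_onsets: Sequence[float] = OP_ONSETS_GA,
              paleo_fix_on: float = PALEO_FIX_ON_GA) -> list[Scenario]:
    """Metabolic-onset sweep: {Eoarchean fixation, Palaeoarchean fixation,
    never} x six oxygenic-photosynthesis onsets (18 scenarios)."""
    fix_cases = [("eofix", 3.8), ("paleofix", paleo_fix_on), ("nofix", None)]
    kw = {"params": params} if params is not None else {}
    return [
        Scenario(id=f"{label}_op{op:g}", t_fix_on=fix_on, t_op_on=op, **kw)
        for label, fix_on in fix_cases
        for op in op_onsets
    ]


def fig3_grid(params: Optional[Params] = None,
              op_onsets: Sequence[float] = OP_ONSETS_GA,
              p_multipliers: Sequence[float] = (0.5, 1.0, 2.0)) -> list[Scenario]:
    """Phosphorus-sensitivity sweep: mantle-P multiplier {0.5, 1, 2} x six
    oxygenic-photosynthesis onsets, N2 fixation fixed at 3.8 Ga."""
    kw = {"params": params} if params is not None else {}
    return [
        Scenario(id=f"p{mult:g}_op{op:g}", t_fix_on=3.8, t_op_on=op,
                 p_multiplier=mult, **kw)
        for mult in p_multipliers
        for op in op_onsets
    ]


def sample_scenarios(n: int, seed: int, params: Optional[Params] = None) -> list[Scenario]:
    """Randomized scenarios for property tests: onsets uniform on
    [2.5, 3.8] Ga, p_multiplier log-uniform on [0.25, 4]."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    kw = {"params": params} if params is not None else {}
    out = []
    for i in range(n):
        fix = float(rng.uniform(2.5, 3.8))
        op = float(rng.uniform(2.5, 3.8))
        mult = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
        out.append(Scenario(id=f"sample{i:03d}", t_fix_on=round(fix, 6),
                            t_op_on=round(op, 6), p_multiplier=round(mult, 6),
                            seed=seed, **kw))
    return out
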