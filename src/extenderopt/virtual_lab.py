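"""Synthetic stand-in for the wet lab: a motility response surface plus noise.

The virtual lab replaces the freeze–thaw assay with a configurable
ground-truth surface mapping an extender formulation to post-thaw total
motility (percent, clamped to [0, 100]) and a two-level noise model for the
dominant sources of variability in semen cryopreservation: among-bull
differences and within-bull straw-to-straw scatter.

The default benchmark surface encodes, as ground truth, the qualitative
structure the optimization is expected to discover in real campaigns:

* concave single-component optima (Gaussian bumps) for buffer, egg yolk,
  glycerol, sugars, CLC and melatonin;
* an antagonistic glycerol × ethylene-glycol interaction plus a monotone
  ethylene-glycol penalty, so the two permeating cryoprotectants are
  redundant-to-harmful in combination and the optimum contains no ethylene
  glycol;
* fructose with a small amplitude (dispensable: formulations without it are
  barely worse);
* a linear nerve-growth-factor penalty (the additive is detrimental).

Because main effects, penalties and interaction terms can be maximized
coordinate-wise under the constraints below, the surface's global argmax is
known in closed form and exposed for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .formulation_space import (
    Formulation,
    FormulationSpace,
    control_extender,
    default_space,
    sample_formulations,
    validate,
)


@dataclass(frozen=True)
class Bump:
    """Concave single-component effect: amplitude · exp(−((x−optimum)/width)²/2)."""

    optimum: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("bump width must be positive")


@dataclass(frozen=True)
class ResponseSurfaceParams:
    """Parameters of the noiseless ground-truth motility surface.

    ``interactions`` are signed coefficients on products of min–max-normalized
    concentrations; ``penalties`` are linear slopes on normalized
    concentrations (motility % lost at the upper bound).
    """

    baseline: float = 12.0
    effects: Mapping[str, Bump] = field(default_factory=dict)
    interactions: tuple[tuple[str, str, float], ...] = ()
    penalties: Mapping[str, float] = field(default_factory=dict)
    floor: float = 0.0
    ceiling: float = 100.0

    def __post_init__(self) -> None:
        if not (self.floor <= self.baseline <= self.ceiling):
            raise ConfigError("baseline must lie within [floor, ceiling]")


def default_surface() -> ResponseSurfaceParams:
    """The benchmark surface used by tests and the shipped campaign config.

    Calibrated so that the control extender's true motility is in the mid-60s
    (matching the configured 60–70 % control median) and the global maximum is
    75 %, leaving headroom the optimizer must close.
    """
    return ResponseSurfaceParams(
        baseline=12.0,
        effects={
            "tris": Bump(optimum=30.0, width=15.0, amplitude=10.0),
            "egg_yolk": Bump(optimum=18.0, width=8.0, amplitude=15.0),
            "milk": Bump(optimum=5.0, width=5.0, amplitude=3.0),
            "fructose": Bump(optimum=0.5, width=0.5, amplitude=2.0),
            "glycerol": Bump(optimum=6.0, width=2.5, amplitude=20.0),
            "trehalose": Bump(optimum=60.0, width=40.0, amplitude=6.0),
            "clc": Bump(optimum=0.75, width=0.3, amplitude=4.0),
            "melatonin": Bump(optimum=2.5, width=0.5, amplitude=3.0),
        },
        interactions=(("glycerol", "ethylene_glycol", -15.0),),
        penalties={"ethylene_glycol": 6.0, "ngf": 10.0},
    )


def _normalized(value: float, space: FormulationSpace, name: str) -> float:
    c = space[name]
    if c.degenerate:
        return 0.0
    return (value - c.lower) / (c.upper - c.lower)


def true_motility(
    f: Formulation, params: ResponseSurfaceParams, space: FormulationSpace
) -> float:
    """Deterministic noiseless motility (%) of a formulation."""
    y = params.baseline
    for name, bump in params.effects.items():
        x = f.value(name, space)
        y += bump.amplitude * np.exp(-0.5 * ((x - bump.optimum) / bump.width) ** 2)
    for a, b, coeff in params.interactions:
        y += coeff * _normalized(f.value(a, space), space, a) * _normalized(
            f.value(b, space), space, b
        )
    for name, slope in params.penalties.items():
        y -= slope * _normalized(f.value(name, space), space, name)
    return float(np.clip(y, params.floor, params.ceiling))


def surface_argmax(
    params: ResponseSurfaceParams, space: FormulationSpace
) -> Formulation:
    """Closed-form global argmax of the noiseless surface.

    Valid when every term can be maximized coordinate-wise: penalized
    components carry no bump, every interaction coefficient is non-positive,
    and each interaction involves at least one component whose optimum sits at
    its (zero-normalized) lower bound.  Raises :class:`ConfigError` otherwise
    rather than silently returning a wrong point.
    """
    conc = space.lower.copy()
    deg = space.degenerate & space.active
    conc[deg] = space.lower[deg]
    for name, bump in params.effects.items():
        if name in params.penalties:
            raise ConfigError(
                f"{name} has both a bump and a penalty; argmax not separable"
            )
        j = space.index(name)
        conc[j] = float(np.clip(bump.optimum, space.lower[j], space.upper[j]))
    for a, b, coeff in params.interactions:
        if coeff > 0:
            raise ConfigError("positive interaction; argmax not separable")
        if all(_normalized(conc[space.index(n)], space, n) > 0 for n in (a, b)):
            raise ConfigError(
                f"interaction ({a}, {b}) does not vanish at the candidate argmax"
            )
    conc[~space.active] = 0.0
    f = Formulation("argmax", conc, provenance="manual")
    if validate(f, space):
        raise ConfigError("candidate argmax violates the space bounds")
    return f


def surface_max(params: ResponseSurfaceParams, space: FormulationSpace) -> float:
    """Known maximum value of the noiseless surface."""
    return true_motility(surface_argmax(params, space), params, space)


# --------------------------------------------------------------------------
# Noise model and assay simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Two-level measurement model: among-bull and within-bull (straw) scatter.

    The bull effect is additive and shared between a treatment straw and the
    split-sample control straw of the same bull, which is what makes the
    relative-motility metric variance-reducing.  Simulated motilities are
    clamped to [0, 100] after all noise is added.
    """

    sd_bull: float = 5.0
    sd_within: float = 3.0

    def __post_init__(self) -> None:
        if self.sd_bull < 0 or self.sd_within < 0:
            raise ConfigError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class MotilityRecord:
    """One straw measurement with its split-sample control."""

    generation: int
    formulation_id: str
    bull_id: str
    replicate: int
    total_motility: float
    control_motility: float


RECORD_COLUMNS = [
    "generation",
    "formulation_id",
    "bull_id",
    "replicate",
    "total_motility",
    "control_motility",
]


def records_to_frame(records: Sequence[MotilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.generation, r.formulation_id, r.bull_id, r.replicate,
             r.total_motility, r.control_motility)
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def _clamp(value: float, params: ResponseSurfaceParams) -> float:
    return float(np.clip(value, params.floor, params.ceiling))


def simulate_assay(
    f: Formulation,
    bulls: Sequence[str],
    replicates: int,
    params: ResponseSurfaceParams,
    noise: NoiseModel,
    space: FormulationSpace,
    rng: np.random.Generator,
    generation: int = 1,
    control: Formulation | None = None,
    bull_effects: Mapping[str, float] | None = None,
) -> list[MotilityRecord]:
    """Simulate one formulation's straws across bulls, with split-sample controls.

    One record per (bull, replicate).  When ``bull_effects`` is supplied the
    same draws can be shared across the formulations of a generation.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    control = control if control is not None else control_extender(space)
    truth_t = true_motility(f, params, space)
    truth_c = true_motility(control, params, space)
    records = []
    for bull in bulls:
        if bull_effects is not None:
            b = bull_effects[bull]
        else:
            b = rng.normal(0.0, noise.sd_bull) if noise.sd_bull > 0 else 0.0
        for rep in range(1, replicates + 1):
            e_t = rng.normal(0.0, noise.sd_within) if noise.sd_within > 0 else 0.0
            e_c = rng.normal(0.0, noise.sd_within) if noise.sd_within > 0 else 0.0
            records.append(
                MotilityRecord(
                    generation=generation,
                    formulation_id=f.id,
                    bull_id=str(bull),
                    replicate=rep,
                    total_motility=_clamp(truth_t + b + e_t, params),
                    control_motility=_clamp(truth_c + b + e_c, params),
                )
            )
    return records


def simulate_generation(
    formulations: Sequence[Formulation],
    bulls: Sequence[str],
    replicates: int,
    params: ResponseSurfaceParams,
    noise: NoiseModel,
    space: FormulationSpace,
    rng: np.random.Generator,
    generation: int,
    control: Formulation | None = None,
) -> list[MotilityRecord]:
    """Assay a whole generation: bull effects drawn once and shared."""
    control = control if control is not None else control_extender(space)
    effects = {
        str(b): (rng.normal(0.0, noise.sd_bull) if noise.sd_bull > 0 else 0.0)
        for b in bulls
    }
    records: list[MotilityRecord] = []
    for f in formulations:
        records.extend(
            simulate_assay(
                f, bulls, replicates, params, noise, space, rng,
                generation=generation, control=control, bull_effects=effects,
            )
        )
    return records


def make_study_fixture(
    n_generations: int,
    formulations_per_gen: int = 8,
    bulls_per_gen: int = 4,
    replicates: int = 3,
    params: ResponseSurfaceParams | None = None,
    noise: NoiseModel | None = None,
    space: FormulationSpace | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate study-shaped ledgers: random formulations plus their assays.

    Defaults reproduce the per-generation design of 8 candidate extenders ×
    4 bulls × 3 straw replicates with a split-sample control.  Returns
    ``(formulations_ledger, motility_ledger)``; both have headers even when
    ``n_generations == 0``.
    """
    from .formulation_space import formulations_to_frame  # local: ledger schema

    space = space or default_space()
    params = params or default_surface()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    form_frames, records = [], []
    for g in range(1, n_generations + 1):
        formulations = sample_formulations(
            space, formulations_per_gen, rng, id_prefix=f"g{g}_f"
        )
        form_frames.append(formulations_to_frame(formulations, space, generation=g))
        bulls = [f"bull_{g}_{i}" for i in range(1, bulls_per_gen + 1)]
        records.extend(
            simulate_generation(
                formulations, bulls, replicates, params, noise, space, rng, g
            )
        )
    if form_frames:
        formulations_df = pd.concat(form_frames, ignore_index=True)
    else:
        formulations_df = formulations_to_frame([], space, generation=0).iloc[0:0]
    return formulations_df, records_to_frame(records)
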