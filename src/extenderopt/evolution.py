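"""Differential evolution (DE/rand/1/bin) over the formulation space.

Strategy: for each target vector, three distinct donors r1, r2, r3 are drawn
from the rest of the population and a trial coordinate is formed as
``r3 + F · (r1 − r2)`` with probability CR (binomial crossover, one forced
mutated coordinate per trial so a trial never equals its target exactly).
After a configurable generation, each mutated coordinate additionally
receives a jitter term ``reference · U(−jitter_fraction, +jitter_fraction)``
to re-inject variation into a converging population.  Out-of-bounds trial
coordinates are clipped to the component bounds; frozen and deactivated
components are never touched.

Selection is pooled top-N elitism over parents ∪ trials (ties in favour of
trial vectors, then by formulation id); classic per-index pairwise
replacement is available as an option.  Convergence is declared when a
Kruskal–Wallis omnibus test across the last few generations' scores finds no
location difference (the trajectory has plateaued).

The RNG draw order is part of the module contract (donor triple via
``rng.choice`` without replacement, then the forced-coordinate index, then
per mutable coordinate one uniform for the crossover decision and, when
jitter is active, one uniform for the jitter multiplier), so a brute-force
oracle can replay the identical stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, ScoringError
from .formulation_space import (
    Formulation,
    FormulationSpace,
    clip_to_bounds,
    sample_formulations,
)


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings.

    F and CR defaults follow the campaign protocol (mutation factor 0.9,
    crossover rate 0.5); the reference-jitter modification switches on for
    generations strictly greater than ``jitter_after_generation``.
    """

    population_size: int = 8
    F: float = 0.9
    CR: float = 0.5
    jitter_after_generation: int = 10
    jitter_fraction: float = 0.10
    seed: int = 0
    candidate_oversampling: int = 4
    selection: str = "pooled_top"  # or "pairwise"

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ConfigError("DE needs a population of at least 4")
        if not (0 < self.CR <= 1):
            raise ConfigError("CR must be in (0, 1]")
        if self.F <= 0:
            raise ConfigError("F must be positive")
        if self.candidate_oversampling < 1:
            raise ConfigError("candidate_oversampling must be >= 1")


@dataclass
class Population:
    """A generation's members with optional aligned scores."""

    generation: int
    members: list[Formulation]
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if len(self.scores) != len(self.members):
                raise ScoringError("scores do not align 1:1 with members")

    def __len__(self) -> int:
        return len(self.members)


def init_population(
    space: FormulationSpace, cfg: DEConfig, rng: np.random.Generator | None = None
) -> Population:
    """Space-filling initial population (per-component Latin-hypercube strata)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    members = sample_formulations(
        space, cfg.population_size, rng, provenance="initial", id_prefix="g1_f"
    )
    return Population(generation=1, members=members)


def apply_reference_jitter(
    value: float, ref: float, cfg: DEConfig, rng: np.random.Generator
) -> float:
    """Add ``ref · U(−jitter_fraction, +jitter_fraction)`` to a coordinate."""
    return value + ref * rng.uniform(-cfg.jitter_fraction, cfg.jitter_fraction)


def mutate_rand_1_bin(
    pop: Population,
    cfg: DEConfig,
    space: FormulationSpace,
    rng: np.random.Generator,
    generation: int,
    n_trials: int | None = None,
    refs: np.ndarray | None = None,
) -> Population:
    """Generate a trial population from ``pop`` by DE/rand/1/bin.

    ``n_trials`` defaults to the population size; oversampled trial pools
    (for surrogate screening) cycle through targets in order.  ``refs``
    override the per-component jitter reference values (default: the space's
    reference column).
    """
    n = len(pop)
    if n < 4:
        raise ConfigError("DE mutation needs at least 4 members")
    n_trials = n_trials if n_trials is not None else n
    refs = np.asarray(refs, dtype=float) if refs is not None else space.reference
    mut_idx = np.flatnonzero(space.mutable)
    jitter_on = generation > cfg.jitter_after_generation
    vectors = np.stack([m.concentrations for m in pop.members])
    trials: list[Formulation] = []
    for t in range(n_trials):
        i = t % n
        others = np.array([j for j in range(n) if j != i])
        r1, r2, r3 = rng.choice(others, size=3, replace=False)
        j_rand = int(rng.integers(len(mut_idx)))
        trial = vectors[i].copy()
        for pos, j in enumerate(mut_idx):
            u = rng.random()
            if u < cfg.CR or pos == j_rand:
                v = vectors[r3, j] + cfg.F * (vectors[r1, j] - vectors[r2, j])
                if jitter_on:
                    v = apply_reference_jitter(v, refs[j], cfg, rng)
                trial[j] = v
        f = Formulation(f"g{generation}_t{t}", trial, provenance="mutant")
        trials.append(clip_to_bounds(f, space))
    return Population(generation=generation, members=trials)


def select_top(parents: Population, trials: Population, k: int) -> Population:
    """Keep the k highest-scoring formulations from parents ∪ trials.

    Ties are broken in favour of trial vectors, then by formulation id.
    """
    for p in (parents, trials):
        if p.scores is None:
            raise ScoringError("both populations must be scored before selection")
    pool = [
        (float(s), 1, m.id, m)  # 1 = trial, sorts before parents on ties
        for m, s in zip(trials.members, trials.scores)
    ] + [
        (float(s), 0, m.id, m)
        for m, s in zip(parents.members, parents.scores)
    ]
    pool.sort(key=lambda item: (-item[0], -item[1], item[2]))
    chosen = pool[:k]
    return Population(
        generation=trials.generation,
        members=[m for *_, m in chosen],
        scores=np.array([s for s, *_ in chosen]),
    )


def select_pairwise(parents: Population, trials: Population) -> Population:
    """Classic DE replacement: trial i survives iff it scores >= parent i."""
    for p in (parents, trials):
        if p.scores is None:
            raise ScoringError("both populations must be scored before selection")
    if len(parents) != len(trials):
        raise ConfigError("pairwise selection needs equal-sized populations")
    members, scores = [], []
    for pm, ps, tm, ts in zip(
        parents.members, parents.scores, trials.members, trials.scores
    ):
        if ts >= ps:
            members.append(tm)
            scores.append(ts)
        else:
            members.append(pm)
            scores.append(ps)
    return Population(trials.generation, members, np.array(scores))


def check_convergence(
    generation_scores: Sequence[np.ndarray], alpha: float = 0.05
) -> bool:
    """Plateau test: Kruskal–Wallis across recent generations' scores.

    Returns True (converged) when the omnibus test finds no significant
    location difference, i.e. p >= alpha.
    """
    from .equivstats import kruskal_wallis  # local import to avoid cycle

    if len(generation_scores) < 2:
        raise ConfigError("convergence check needs at least 2 generations")
    result = kruskal_wallis([np.asarray(g, dtype=float) for g in generation_scores])
    return bool(result.p_value >= alpha)
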