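"""Design space for cryopreservation extender formulations.

An extender is described by the concentration of each of its media components
(buffer, membrane stabilizers, permeating and non-permeating cryoprotectants,
sugars, antioxidants).  The optimization treats each component as one bounded
design variable; units are kept per component exactly as a bench protocol
would state them (percent v/v, percent w/v, mM, mg/mL), so a formulation is a
concentration vector aligned to an ordered :class:`FormulationSpace`.

The module also covers the plumbing around that representation: loading and
serializing the space definition, validating and clipping concentration
vectors, converting a formulation into a dispensing recipe for a finite batch
volume, and the constant commercial-style control extender used as the
split-sample reference in every assay.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, BoundsError, RecipeError, SchemaError

VALID_UNITS = frozenset({"percent v/v", "percent w/v", "mM", "mg/mL", "ng/mL"})

#: molar masses (g/mol) used by the default dispensing rules
MOLAR_MASS = {
    "fructose": 180.156,
    "trehalose": 342.296,
    "glutathione": 307.32,
    "melatonin": 232.28,
}

#: 1 % w/v of fructose corresponds to this many mM
FRUCTOSE_MM_PER_PERCENT = 10_000.0 / MOLAR_MASS["fructose"]


@dataclass(frozen=True)
class ComponentSpec:
    """One design variable: a media component with bounds and a reference value.

    A frozen component (one held at a constant concentration) is encoded with
    ``lower == upper``.  A component removed mid-campaign keeps its column in
    every ledger with ``active=False`` and value 0.
    """

    name: str
    unit: str
    lower: float
    upper: float
    reference: float
    active: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("component name must be non-empty")
        if self.unit not in VALID_UNITS:
            raise SchemaError(f"unknown unit {self.unit!r} for component {self.name!r}")
        if self.lower > self.upper:
            raise BoundsError(f"{self.name}: lower {self.lower} > upper {self.upper}")
        if not (self.lower <= self.reference <= self.upper):
            raise BoundsError(
                f"{self.name}: reference {self.reference} outside "
                f"[{self.lower}, {self.upper}]"
            )

    @property
    def degenerate(self) -> bool:
        """True for a frozen component (zero-width range)."""
        return self.lower == self.upper


@dataclass(frozen=True)
class FormulationSpace:
    """Ordered collection of :class:`ComponentSpec`; order is stable across I/O."""

    components: tuple[ComponentSpec, ...]
    version_tag: str = "v1"

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise SchemaError("a formulation space needs at least one component")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate component names in space")

    def __len__(self) -> int:
        return len(self.components)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, name: str) -> ComponentSpec:
        return self.components[self.index(name)]

    @property
    def lower(self) -> np.ndarray:
        return np.array([c.lower for c in self.components], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([c.upper for c in self.components], dtype=float)

    @property
    def reference(self) -> np.ndarray:
        return np.array([c.reference for c in self.components], dtype=float)

    @property
    def active(self) -> np.ndarray:
        return np.array([c.active for c in self.components], dtype=bool)

    @property
    def degenerate(self) -> np.ndarray:
        return np.array([c.degenerate for c in self.components], dtype=bool)

    @property
    def mutable(self) -> np.ndarray:
        """Coordinates the optimizer is allowed to vary: active, non-frozen."""
        return self.active & ~self.degenerate

    def with_deactivated(self, names: Iterable[str]) -> "FormulationSpace":
        """Return a copy with the named components deactivated (column kept)."""
        names = set(names)
        missing = names - set(self.names)
        if missing:
            raise SchemaError(f"cannot deactivate unknown components: {sorted(missing)}")
        comps = tuple(
            replace(c, active=False) if c.name in names else c for c in self.components
        )
        return FormulationSpace(comps, version_tag=self.version_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "unit": [c.unit for c in self.components],
                "lower": self.lower,
                "upper": self.upper,
                "reference": self.reference,
                "active": self.active.astype(int),
            }
        )

    def write(self, path_or_buffer) -> None:
        self.to_frame().to_csv(path_or_buffer, index=False)


@dataclass(frozen=True)
class Formulation:
    """One candidate extender: a concentration vector aligned to a space."""

    id: str
    concentrations: np.ndarray
    provenance: str = "manual"  # one of {initial, mutant, manual, control}

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )

    def value(self, name: str, space: FormulationSpace) -> float:
        return float(self.concentrations[space.index(name)])

    def with_value(self, name: str, value: float, space: FormulationSpace) -> "Formulation":
        conc = self.concentrations.copy()
        conc[space.index(name)] = value
        return Formulation(self.id, conc, self.provenance)


def load_space(table) -> FormulationSpace:
    """Load a formulation space from delimited text (path, buffer or str).

    Required columns: ``name, unit, lower, upper, reference``; optional
    ``active`` (default 1).  Duplicate names, empty tables and inverted
    bounds are rejected.
    """
    if isinstance(table, str) and "\n" in table:
        table = io.StringIO(table)
    df = pd.read_csv(table)
    required = {"name", "unit", "lower", "upper", "reference"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"space table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise SchemaError("space table has no components")
    if "active" not in df.columns:
        df["active"] = 1
    comps = tuple(
        ComponentSpec(
            name=str(r["name"]),
            unit=str(r["unit"]),
            lower=float(r["lower"]),
            upper=float(r["upper"]),
            reference=float(r["reference"]),
            active=bool(int(r["active"])),
        )
        for r in df.to_dict("records")
    )
    return FormulationSpace(comps)


def default_space() -> FormulationSpace:
    """The 11-component design space shipped with the package.

    Tris, egg yolk, milk, fructose, glycerol, ethylene glycol, trehalose,
    cholesterol-loaded cyclodextrin (CLC), glutathione (frozen at 0.5 mM),
    melatonin and nerve growth factor (NGF).
    """
    with resources.files("extenderopt.data").joinpath("design_space.csv").open() as fh:
        return load_space(fh)


def load_top_extenders() -> pd.DataFrame:
    """Read-only fixture: dispensing recipes of the five top extenders."""
    with resources.files("extenderopt.data").joinpath("top_extenders.csv").open() as fh:
        return pd.read_csv(fh)


def validate(f: Formulation, space: FormulationSpace) -> list[str]:
    """Return a list of human-readable bound violations (empty iff valid).

    A misaligned vector raises :class:`AlignmentError` instead of reporting,
    since none of the per-component checks are meaningful then.
    """
    if len(f.concentrations) != len(space):
        raise AlignmentError(
            f"formulation {f.id!r} has {len(f.concentrations)} concentrations "
            f"for a {len(space)}-component space"
        )
    violations: list[str] = []
    for c, v in zip(space.components, f.concentrations):
        if not c.active:
            if v != 0.0:
                violations.append(f"{c.name}: inactive component must be 0, got {v}")
        elif c.degenerate:
            if v != c.lower:
                violations.append(f"{c.name}: frozen at {c.lower}, got {v}")
        elif not (c.lower <= v <= c.upper):
            violations.append(f"{c.name}: {v} outside [{c.lower}, {c.upper}]")
    return violations


def clip_to_bounds(f: Formulation, space: FormulationSpace) -> Formulation:
    """Project every coordinate onto its component's bounds (idempotent).

    Inactive components are forced to 0; frozen components to their frozen
    value (both are exact assignments, not numerical clips).
    """
    if len(f.concentrations) != len(space):
        raise AlignmentError("formulation/space length mismatch")
    conc = np.clip(f.concentrations, space.lower, space.upper)
    conc[~space.active] = 0.0
    deg = space.degenerate & space.active
    conc[deg] = space.lower[deg]
    return Formulation(f.id, conc, f.provenance)


def sample_formulations(
    space: FormulationSpace,
    n: int,
    rng: np.random.Generator,
    provenance: str = "initial",
    id_prefix: str = "f",
) -> list[Formulation]:
    """Draw ``n`` valid formulations by per-component Latin-hypercube stratification.

    Each mutable component's ``n`` values fall one per stratum of its range
    (independent random stratum orderings per component), which guarantees
    range coverage even at small ``n`` in many dimensions.
    """
    lower, upper = space.lower, space.upper
    x = np.tile(lower, (n, 1))
    for j in range(len(space)):
        if not space.mutable[j]:
            x[:, j] = 0.0 if not space.active[j] else lower[j]
            continue
        strata = rng.permutation(n)
        u = rng.uniform(size=n)
        x[:, j] = lower[j] + (strata + u) / n * (upper[j] - lower[j])
    return [
        Formulation(f"{id_prefix}{i}", x[i], provenance=provenance) for i in range(n)
    ]


# --------------------------------------------------------------------------
# Batch recipes (dispensing amounts for a finite batch volume)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DispenseRule:
    """How one component's concentration converts into a dispensed amount.

    kinds:
      ``volume``        percent v/v  -> mL of the component
      ``mass_w_v``      percent w/v  -> mg of solid
      ``mass_mM``       mM           -> mg of solid via ``molar_mass``
      ``mass_per_mL``   mg/mL        -> mg of solid
      ``stock_volume``  mM           -> µL of a stock at ``stock_mM``
    """

    kind: str
    molar_mass: float | None = None
    stock_mM: float | None = None


def default_dispense_rules(space: FormulationSpace) -> dict[str, DispenseRule]:
    """Default conversion table for the shipped space.

    Stock concentrations for glutathione and melatonin are configurable
    assumptions, not protocol facts.
    """
    by_name = {
        "trehalose": DispenseRule("mass_mM", molar_mass=MOLAR_MASS["trehalose"]),
        "glutathione": DispenseRule("stock_volume", stock_mM=800.0),
        "melatonin": DispenseRule("stock_volume", stock_mM=2500.0),
    }
    by_unit = {
        "percent v/v": DispenseRule("volume"),
        "percent w/v": DispenseRule("mass_w_v"),
        "mg/mL": DispenseRule("mass_per_mL"),
        "ng/mL": DispenseRule("mass_per_mL"),
        "mM": DispenseRule("mass_mM", molar_mass=1.0),
    }
    return {
        c.name: by_name.get(c.name, by_unit[c.unit]) for c in space.components
    }


@dataclass(frozen=True)
class Amount:
    value: float
    unit: str  # mL, mg, uL


@dataclass(frozen=True)
class BatchRecipe:
    """Dispensing amounts for one batch; water fills to the batch volume."""

    batch_volume_mL: float
    amounts: Mapping[str, Amount]
    water_mL: float

    def volume_fraction(self, name: str) -> float:
        """v/v fraction of a liquid component (dimensionless, of the batch)."""
        amt = self.amounts[name]
        if amt.unit != "mL":
            raise RecipeError(f"{name} is dispensed as {amt.unit}, not a liquid volume")
        return amt.value / self.batch_volume_mL


def to_recipe(
    f: Formulation,
    batch_volume_mL: float,
    space: FormulationSpace,
    rules: Mapping[str, DispenseRule] | None = None,
) -> BatchRecipe:
    """Convert a formulation into per-component dispensed amounts.

    Water is the filler: ``batch_volume − Σ liquid volumes``.  Raises
    :class:`RecipeError` when the liquids alone exceed the batch volume.
    """
    if batch_volume_mL <= 0:
        raise RecipeError("batch volume must be positive")
    if len(f.concentrations) != len(space):
        raise AlignmentError("formulation/space length mismatch")
    rules = rules or default_dispense_rules(space)
    amounts: dict[str, Amount] = {}
    liquid_mL = 0.0
    for c, conc in zip(space.components, f.concentrations):
        rule = rules[c.name]
        if rule.kind == "volume":
            vol = conc / 100.0 * batch_volume_mL
            amounts[c.name] = Amount(vol, "mL")
            liquid_mL += vol
        elif rule.kind == "mass_w_v":
            # 1 % w/v = 10 mg per mL of batch
            amounts[c.name] = Amount(conc * 10.0 * batch_volume_mL, "mg")
        elif rule.kind == "mass_mM":
            mg = conc * (rule.molar_mass or 1.0) * batch_volume_mL / 1000.0
            amounts[c.name] = Amount(mg, "mg")
        elif rule.kind == "mass_per_mL":
            amounts[c.name] = Amount(conc * batch_volume_mL, "mg")
        elif rule.kind == "stock_volume":
            if not rule.stock_mM:
                raise RecipeError(f"{c.name}: stock concentration required")
            uL = conc * batch_volume_mL / rule.stock_mM * 1000.0
            amounts[c.name] = Amount(uL, "uL")
            liquid_mL += uL / 1000.0
        else:  # pragma: no cover - guarded by DispenseRule docstring
            raise RecipeError(f"unknown dispense rule kind {rule.kind!r}")
    water = batch_volume_mL - liquid_mL
    if water < 0:
        raise RecipeError(
            f"liquid volumes ({liquid_mL:.3f} mL) exceed batch volume "
            f"({batch_volume_mL} mL)"
        )
    return BatchRecipe(batch_volume_mL, amounts, water)


# --------------------------------------------------------------------------
# Control extender
# --------------------------------------------------------------------------

#: molar composition of the commercial-style control buffer (per litre)
CONTROL_RECIPE_MM = {"tris": 200.0, "citric_acid": 66.7, "fructose": 55.5}
#: fresh egg yolk fraction of the control, % v/v (200 mL per 1 L)
CONTROL_EGG_YOLK_PERCENT = 20.0
#: glycerol fraction of the control, % v/v (industry-standard level)
CONTROL_GLYCEROL_PERCENT = 6.0

_CONTROL_VALUES = {
    "tris": 30.0,  # buffer stock fraction, % v/v
    "egg_yolk": CONTROL_EGG_YOLK_PERCENT,
    "milk": 0.0,
    "fructose": 55.5 / FRUCTOSE_MM_PER_PERCENT,  # 55.5 mM as % w/v
    "glycerol": CONTROL_GLYCEROL_PERCENT,
    "ethylene_glycol": 0.0,
    "trehalose": 0.0,
    "clc": 0.5,
    "glutathione": 0.5,
    "melatonin": 2.0,
    "ngf": 0.0,
}


def control_extender(space: FormulationSpace | None = None) -> Formulation:
    """The constant split-sample control extender (never touched by the optimizer).

    A Tris/citric-acid buffer with 55.5 mM fructose, 20 % v/v egg yolk and 6 %
    v/v glycerol.  Returned aligned to ``space`` (default shipped space);
    components the control does not contain sit at their lower bound.
    """
    space = space or default_space()
    conc = space.lower.copy()
    for name, value in _CONTROL_VALUES.items():
        if name in space.names:
            conc[space.index(name)] = value
    return Formulation("control", conc, provenance="control")


def fructose_percent_to_mM(percent_w_v: float) -> float:
    """Convert fructose % w/v into mM (10 g/L per percent)."""
    return percent_w_v * FRUCTOSE_MM_PER_PERCENT


def factorial_design_size(space: FormulationSpace, levels: int = 3) -> int:
    """Number of treatment combinations in a full factorial over the space."""
    return levels ** len(space)


def formulations_to_frame(
    formulations: Sequence[Formulation],
    space: FormulationSpace,
    generation: int | None = None,
) -> pd.DataFrame:
    """Ledger-schema frame: generation, formulation_id, provenance, components."""
    rows = []
    for f in formulations:
        row = {"formulation_id": f.id, "provenance": f.provenance}
        if generation is not None:
            row["generation"] = generation
        row.update(dict(zip(space.names, f.concentrations)))
        rows.append(row)
    cols = (["generation"] if generation is not None else []) + [
        "formulation_id",
        "provenance",
    ] + space.names
    return pd.DataFrame(rows, columns=cols)
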