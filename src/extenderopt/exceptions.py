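"""Exception hierarchy shared across the package."""


class ExtenderOptError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ExtenderOptError):
    """A delimited-text table is missing required columns or rows."""


class BoundsError(ExtenderOptError):
    """A component's bounds are inconsistent (lower > upper, reference outside)."""


class AlignmentError(ExtenderOptError):
    """A concentration vector does not align with its formulation space."""


class RecipeError(ExtenderOptError):
    """A batch recipe is infeasible (liquid volumes exceed the batch volume)."""


class ConfigError(ExtenderOptError):
    """An algorithm configuration violates its invariants."""


class DataError(ExtenderOptError):
    """Input data is empty, degenerate or otherwise unusable for a statistic."""


class ScoringError(ExtenderOptError):
    """A selection step was attempted on an unscored population."""


class StateError(ExtenderOptError):
    """An operation was called on an object in the wrong state (e.g. unfitted model)."""


class IngestError(ExtenderOptError):
    """An external motility ledger failed validation."""
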