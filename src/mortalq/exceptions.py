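"""Exception hierarchy for mortalq."""


class MortalQError(Exception):
    """Base class for all mortalq errors."""


class ConfigurationError(MortalQError):
    """Invalid configuration value; the message names the offending field."""


class DataError(MortalQError):
    """Input data violates a contract (schema, invariants, required rows)."""


class SchemaError(DataError):
    """A required column or field is absent."""


class SeparationError(MortalQError):
    """Perfect separation (or a degenerate outcome) in a logistic model.

    Suggests enabling the penalized fallback.
    """


class ConvergenceError(MortalQError):
    """An iterative solver failed to converge."""


class SolverError(MortalQError):
    """The LP (or fallback) solver reported failure."""


class DegenerateDistributionError(MortalQError):
    """A bootstrap replicate distribution has zero spread where spread is required."""
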