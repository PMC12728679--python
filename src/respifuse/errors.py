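"""Exception hierarchy shared across the pipeline."""


class RespifuseError(Exception):
    """Base class for all package errors."""


class SpecificationError(RespifuseError, ValueError):
    """Invalid cohort or run specification (non-positive counts, rates, ...)."""


class ConfigurationError(RespifuseError, ValueError):
    """A module configuration violates its invariants."""


class InputError(RespifuseError, ValueError):
    """An input signal or table fails a precondition."""


class AlignmentError(RespifuseError, ValueError):
    """Row/subject alignment broken between tables or sequences."""


class SchemaError(RespifuseError, ValueError):
    """Column names do not match the expected schema."""


class DegenerateSolutionError(RespifuseError, RuntimeError):
    """An optimizer collapsed to a degenerate (all-zero) solution."""


class DivergenceError(RespifuseError, RuntimeError):
    """Training diverged to non-finite loss."""
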