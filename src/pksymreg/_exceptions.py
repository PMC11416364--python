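"""Exception hierarchy shared across the package."""


class PkSymRegError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PkSymRegError, ValueError):
    """A PK parameter vector violates positivity/finiteness."""


class DomainError(PkSymRegError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class FormatError(PkSymRegError, ValueError):
    """A file or record violates the documented dialect."""


class StructuralError(PkSymRegError, ValueError):
    """Network dimensions or masks are inconsistent."""


class ScheduleError(PkSymRegError, ValueError):
    """A pruning/fold schedule cannot be executed."""


class TrainingError(PkSymRegError, RuntimeError):
    """Training aborted (e.g. NaN loss)."""


class GenerationError(PkSymRegError, ValueError):
    """Synthetic data generation produced invalid output."""


class EvaluationError(PkSymRegError, ValueError):
    """An expression could not be evaluated (e.g. missing covariate)."""
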