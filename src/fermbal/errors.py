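"""Exception types shared across the pipeline stages."""


class FermbalError(Exception):
    """Base class for all package errors."""


class RegistryError(FermbalError, KeyError):
    """Unknown compound, or a compound failing its registry invariants."""


class BalancingError(FermbalError, ValueError):
    """Reaction template cannot be balanced from element conservation."""


class SimulationError(FermbalError, RuntimeError):
    """The reactor state became unphysical (e.g. a gas pool went negative)."""


class StepSizeError(SimulationError):
    """A liquid concentration went negative within one Euler step."""


class InsufficientDataError(FermbalError, ValueError):
    """Too few samples inside a period to fit or difference anything."""


class InputError(FermbalError, ValueError):
    """Malformed measurement input (non-monotone time, bad fractions, ...)."""


class TracerError(FermbalError, ValueError):
    """Tracer fraction at or below the detection floor; volume unreliable."""


class EstimationError(FermbalError, ValueError):
    """A required quantity (e.g. gas volume) is unavailable for a sample."""


class UncertaintyUnavailableError(FermbalError, ValueError):
    """Too few control intervals to derive a standard error."""


class BookkeepingError(FermbalError, ValueError):
    """Event log does not cover a period needed for gas bookkeeping."""


class CoverageError(FermbalError, ValueError):
    """Inputs do not cover the requested balance period."""


class UndefinedContrastError(FermbalError, ZeroDivisionError):
    """Contrast against a zero or negative control rate."""


class AlignmentError(FermbalError, ValueError):
    """Mismatched period labels / compounds between two rate tables."""


class ValidationError(FermbalError, ValueError):
    """A configuration or specification object failed validation."""
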