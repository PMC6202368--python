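"""Exception hierarchy for the memskin package."""


class MemskinError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MemskinError, ValueError):
    """A physical or stimulus parameter is outside its admissible range."""


class InvalidStateError(MemskinError, ValueError):
    """A circuit state (duct filling, temperature) is outside its admissible range."""


class InvalidSpecError(MemskinError, ValueError):
    """A population specification is inconsistent (e.g. weights not summing to 1)."""


class NumericalFailureError(MemskinError, ArithmeticError):
    """ODE integration produced non-finite values; message names the parameter regime."""


class UnsupportedStimulusError(MemskinError, ValueError):
    """An operation was asked for a stimulus kind it is not defined on."""


class InvalidIndexError(MemskinError, IndexError):
    """Period index outside the recorded range."""


class DegenerateLoopError(MemskinError, ValueError):
    """Loop statistic undefined because a denominator fell below its floor."""


class InvalidPeriodError(MemskinError, ValueError):
    """A period does not support the requested statistic (e.g. branch never
    reaches 0.75 of the voltage amplitude)."""


class InsufficientDataError(MemskinError, ValueError):
    """Too few samples for a geometric operation."""


class RankDeficiencyError(MemskinError, ValueError):
    """Mixed-model design matrix is rank deficient; message names the missing factor."""


class FormatError(MemskinError, ValueError):
    """Recording file violates the versioned on-disk schema."""
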