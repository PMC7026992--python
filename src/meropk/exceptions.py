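"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A structural PK parameter is non-positive or non-finite."""


class InputError(ValueError):
    """Malformed input: unsorted grid, mismatched lengths, bad window, ..."""


class UndefinedRatioError(ZeroDivisionError):
    """Ratio requested with a zero denominator (e.g. zero plasma AUC)."""


class CensoredResultError(ValueError):
    """An operation required quantifiable values but received below-LOQ data."""


class NumericalUnderflowError(ArithmeticError):
    """All mixture likelihoods underflowed; work in log space instead."""
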