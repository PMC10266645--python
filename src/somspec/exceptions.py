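"""Exception hierarchy shared across the package."""


class SomspecError(Exception):
    """Base class for all package errors."""


class ParameterError(SomspecError, ValueError):
    """A function argument violates its contract (bad window, k too large, ...)."""


class DomainError(SomspecError, ValueError):
    """Input values outside the mathematical domain of a transform (e.g. log of 0)."""


class FormatError(SomspecError, ValueError):
    """A spectra table on disk does not match the expected wide-table dialect."""


class DegenerateInputError(SomspecError, ValueError):
    """Statistically degenerate input (zero variance target, constant predictor)."""
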