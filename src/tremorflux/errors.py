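"""Exception hierarchy shared by all tremorflux modules."""


class TremorFluxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TremorFluxError, ValueError):
    """A file does not conform to the expected column layout."""


class ParseError(TremorFluxError, ValueError):
    """A cell could not be converted to a number."""


class EmptyInputError(TremorFluxError, ValueError):
    """A file or sequence contains no data rows."""


class ParameterError(TremorFluxError, ValueError):
    """A parameter violates its contract (range, ordering, domain)."""


class LengthError(TremorFluxError, ValueError):
    """An input sequence is too short for the requested operation."""


class DegenerateSignalError(TremorFluxError, ValueError):
    """A signal is constant/singular where variability is required."""
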