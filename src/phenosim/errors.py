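"""Exception hierarchy.

Every error raised by the library derives from :class:`PhenosimError`, so
callers (and the CLI) can distinguish configuration mistakes from data
problems with a single ``except`` clause.
"""


class PhenosimError(Exception):
    """Base class for all phenosim errors."""


class ParseError(PhenosimError):
    """Malformed coalescent-simulator input.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UnitConversionError(PhenosimError):
    """Position unit conversion attempted without the required locus length."""


class ValidationError(PhenosimError):
    """An in-memory object violates one of its invariants."""


class EligibilityError(PhenosimError):
    """No site (or site pair) satisfies the causal-variant constraints."""


class ModelError(PhenosimError):
    """A trait model is internally inconsistent or degenerate on the data."""


class PairingError(PhenosimError):
    """Diploid pairing requested on an odd number of chromosomes."""


class AscertainmentError(PhenosimError):
    """Fewer cases (or controls) available than requested.

    ``available`` reports how many were present so the user knows to simulate
    a larger population.
    """

    def __init__(self, message: str, available: int | None = None):
        super().__init__(message)
        self.available = available


class SamplingError(PhenosimError):
    """A subsampling request exceeds what the data set provides."""


class ConfigError(PhenosimError):
    """Invalid or contradictory run configuration."""
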