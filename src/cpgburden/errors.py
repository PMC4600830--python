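"""Exception hierarchy shared across the package."""


class CpgBurdenError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(CpgBurdenError, ValueError):
    """A coding-sequence, codon or protein coordinate is out of range."""


class ConfigurationError(CpgBurdenError, ValueError):
    """A run parameter, region name or manifest entry is invalid."""


class DataIntegrityError(CpgBurdenError, ValueError):
    """Input data contradict the transcript model or the cohort manifest."""


class GenerationError(CpgBurdenError, RuntimeError):
    """The synthetic-data generator cannot satisfy a requested site class."""


class UnreachableSignificanceError(CpgBurdenError, ValueError):
    """No control cohort size can make the requested test significant."""
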