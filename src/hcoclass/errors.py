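"""Exception types shared across the package."""


class HcoclassError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HcoclassError, ValueError):
    """A FASTA or table file could not be parsed."""


class ConfigurationError(HcoclassError, ValueError):
    """An anchor profile, scoring scheme or run configuration is invalid."""


class UndefinedSimilarityError(HcoclassError, ZeroDivisionError):
    """Similarity requested for an alignment with an empty query span."""
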