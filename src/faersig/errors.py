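"""Exception hierarchy for the faersig package."""


class FaersigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FaersigError):
    """A configuration value is invalid or inconsistent."""


class IngestionError(FaersigError):
    """A required input file is missing or unreadable."""


class ParseError(FaersigError):
    """Malformed input exceeded the configured tolerance."""


class ValidationError(FaersigError):
    """A data table violates one of its invariants."""


class LookupError_(FaersigError):
    """An identifier does not exist in the referenced vocabulary."""


class FitError(FaersigError):
    """An empirical-Bayes prior fit cannot proceed on this corpus."""
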