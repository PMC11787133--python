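"""Exception hierarchy.

All pipeline failures derive from :class:`TlsQuantError` so callers (and the
CLI) can distinguish validation problems from programming errors.
"""


class TlsQuantError(Exception):
    """Base class for all tlsquant errors."""


class FormatError(TlsQuantError):
    """Malformed input file or table (unknown pixel class, duplicate GMT set...)."""


class ConfigError(TlsQuantError):
    """Invalid or missing configuration value."""


class AnalysisError(TlsQuantError):
    """A computation cannot proceed on this input (no tumor region, empty set...)."""


class GenerationError(TlsQuantError):
    """The synthetic-data generator cannot satisfy the requested geometry."""
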