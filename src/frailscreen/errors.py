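"""Exception hierarchy.

All package errors derive from :class:`FrailscreenError` so callers can
catch one base type; each also subclasses the closest builtin.
"""


class FrailscreenError(Exception):
    """Base class for all frailscreen errors."""


class ConfigurationError(FrailscreenError, ValueError):
    """Invalid configuration (mixture weights, sampling rates, thresholds...)."""


class InputFormatError(FrailscreenError, ValueError):
    """Malformed sensor stream or table (non-monotone timestamps, bad columns)."""


class ScoringError(FrailscreenError, ValueError):
    """Reference-standard input out of range or missing an item."""


class ProtocolError(FrailscreenError, ValueError):
    """Analyzer invoked with inputs missing an upstream processing step."""


class AnalysisError(FrailscreenError, RuntimeError):
    """An analyzer could not produce a result and no fallback is configured."""


class ValidationError(FrailscreenError, ValueError):
    """Diagnostic validation cannot be computed (e.g. single-class condition)."""
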