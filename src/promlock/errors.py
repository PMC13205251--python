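"""Exception hierarchy shared across the pipeline."""


class PromlockError(Exception):
    """Base class for all promlock errors."""


class ConfigError(PromlockError):
    """An invalid configuration value; the message names the offending field."""


class InputValidationError(PromlockError):
    """Malformed input data (duplicate ids, unparseable dates, bad schema)."""


class AnalysisError(PromlockError):
    """A statistical routine was called on degenerate input."""
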