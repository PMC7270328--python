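"""Exception hierarchy shared across the pipeline."""


class ConnharmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConnharmError):
    """Invalid configuration values."""


class DataError(ConnharmError):
    """Malformed or incomplete input data."""


class ParameterError(ConnharmError):
    """Parameter outside its documented range."""


class QualityError(ConnharmError):
    """A subject fails a data-quality gate (e.g. too few frames after scrubbing)."""


class UsageError(ConnharmError):
    """API misuse: wrong call sequence or inconsistent arguments."""


class LeakageError(ConnharmError):
    """Train/test subject bookkeeping violated."""
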