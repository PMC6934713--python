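"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the command-line interface: configuration problems
exit with 2, data problems with 3 (see :mod:`swaylearn.cli`).
"""


class SwaylearnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SwaylearnError):
    """A configuration field is missing, out of range, or inconsistent."""


class DataFormatError(SwaylearnError):
    """A file does not conform to the declared timeseries or manifest dialect."""


class CleaningError(SwaylearnError):
    """A recording cannot be cleaned (e.g. an all-missing channel)."""


class DomainError(SwaylearnError):
    """An argument violates an operation's domain (wrong shape, bad range)."""


class TrainingError(SwaylearnError):
    """A classifier cannot be trained (e.g. single-class training data)."""
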