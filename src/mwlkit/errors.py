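"""Exception hierarchy.

All package-raised errors derive from :class:`MWLError`, so callers can
catch one type at the CLI boundary while tests can assert on the
specific subclass.
"""


class MWLError(Exception):
    """Base class for all mwlkit errors."""


class ConfigError(MWLError):
    """A configuration value is missing, malformed or out of range."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message if key is None else f"{key}: {message}")
        self.key = key


class ScheduleError(ConfigError):
    """The phase schedule is malformed (wrong count, non-positive duration)."""


class ParameterError(MWLError):
    """An operation was called with parameters outside its valid range."""


class MissingChannelError(ParameterError):
    """A required EEG channel label is absent from the recording."""


class MissingStreamError(MWLError):
    """A required input stream/file is absent."""


class AlignmentError(ParameterError):
    """Two series cannot be placed on a common time grid."""


class DegenerateDataError(MWLError):
    """The data admit no defined result (constant series, empty matrix...)."""
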