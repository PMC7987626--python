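"""Exception hierarchy for input validation and pipeline failures."""


class CtcPanelError(Exception):
    """Base class for all package errors."""


class FormatError(CtcPanelError):
    """A table is malformed (missing columns, bad header)."""


class IntegrityError(CtcPanelError):
    """Duplicate keys or mutually inconsistent records."""


class RangeError(CtcPanelError):
    """A value is outside its admissible range."""


class PairingError(CtcPanelError):
    """A sample lacks one of the paired fractions."""


class EvaluationError(CtcPanelError):
    """A rule references data that is not available."""


class DegenerateDataError(CtcPanelError):
    """The input admits no meaningful statistic (empty, constant, ...)."""


class ConfigError(CtcPanelError):
    """A simulation or run configuration is invalid."""
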