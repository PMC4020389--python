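"""Exception hierarchy shared by all pipeline stages."""


class TongueLabError(Exception):
    """Base class for all package errors."""


class FormatError(TongueLabError):
    """Malformed input: wrong channel count, dimension mismatch, bad region."""


class DomainError(TongueLabError):
    """Parameter outside its mathematical domain."""


class ConfigError(TongueLabError):
    """Invalid configuration; the message names the violated field/constraint."""


class SegmentationError(TongueLabError):
    """Automatic segmentation failed; a manual mask is required."""


class FitError(TongueLabError):
    """Degenerate design in a least-squares fit."""


class AnalysisError(TongueLabError):
    """Analysis stage cannot proceed (empty mask, missing group, ...)."""


class StatTestError(TongueLabError):
    """A statistical test's preconditions are violated (constant sample, ...)."""


class SpecError(TongueLabError):
    """Invalid synthetic-phantom or cohort specification."""
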