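"""Exception types shared across the pipeline."""


class CtbsEegError(Exception):
    """Base class for all package errors."""


class ValidationError(CtbsEegError, ValueError):
    """A configuration or argument violates a stated contract."""


class NoAnalyzableDataError(CtbsEegError):
    """Every epoch (or channel) was rejected; downstream stages must refuse
    to run rather than silently emit empty results."""


class DegenerateDataError(CtbsEegError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
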