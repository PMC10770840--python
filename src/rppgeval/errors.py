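"""Structured errors raised by the evaluation pipeline.

Windows or channels that trigger these are excluded from aggregation and
logged with their identity (subject / activity / channel / window) so that
every exclusion is accounted for.
"""

from __future__ import annotations


class RppgEvalError(Exception):
    """Base class for all package errors."""


class ConfigError(RppgEvalError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RppgEvalError):
    """Missing or malformed input data (CLI exit code 3)."""


class StatsPreconditionError(RppgEvalError):
    """A statistical procedure's preconditions are not met (CLI exit code 4)."""


class FlatSignalError(RppgEvalError):
    """Signal has zero interquartile range; robust normalization is undefined.

    Carries the identity of the offending segment so callers can exclude
    and log it.
    """

    def __init__(self, message: str = "flat signal: IQR is zero", *,
                 channel: str | None = None, window: int | None = None,
                 subject: str | None = None, activity: str | None = None):
        self.channel = channel
        self.window = window
        self.subject = subject
        self.activity = activity
        ident = ", ".join(f"{k}={v}" for k, v in
                          [("subject", subject), ("activity", activity),
                           ("channel", channel), ("window", window)]
                          if v is not None)
        super().__init__(f"{message}" + (f" [{ident}]" if ident else ""))


class ZeroVarianceError(RppgEvalError):
    """A correlation was requested on a zero-variance segment."""
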