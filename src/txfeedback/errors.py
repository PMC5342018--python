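"""Exception types shared across the pipeline."""


class TxFeedbackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TxFeedbackError):
    """A configuration object violates its invariants."""


class InputError(TxFeedbackError):
    """An input value or table violates an operation's preconditions."""


class DegeneratePatternError(TxFeedbackError):
    """A pattern row is identically zero and cannot be normalized."""


class NoGenesPassFilterError(TxFeedbackError):
    """Gene filtering removed every gene."""
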