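"""Exception hierarchy.

Each failure class maps to a distinct CLI exit code (see ``cli``):
format problems (bad files), validation problems (bad values),
estimation problems (degenerate designs, empty arms), and inference
problems (bootstrap failure-rate overruns).
"""


class LongmediateError(Exception):
    """Base class for all package errors."""


class FormatError(LongmediateError):
    """A file could not be parsed: missing columns, bad layout."""


class ValidationError(LongmediateError):
    """Parsed data violate an invariant (nonpositive UACR, duplicate visit...)."""


class EstimationError(LongmediateError):
    """A model fit or effect estimate is impossible on the given data."""


class InferenceError(LongmediateError):
    """Bootstrap inference failed (retry budget exhausted)."""
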