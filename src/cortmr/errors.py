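"""Typed signals used across the pipeline.

Empty-result conditions (no instrument survives a filter, too few
instruments for an estimator) are ordinary outcomes of a multi-outcome
study, so they are modelled as dedicated exception types that callers
can catch and record, distinct from hard input errors.
"""


class CortMRError(Exception):
    """Base class for all package errors."""


class InputFormatError(CortMRError):
    """A file or table violates its format contract (hard error)."""


class ConfigError(CortMRError):
    """A configuration value or schema is invalid (hard error)."""


class NoInstrumentsError(CortMRError):
    """A selection step left zero instruments (typed empty-result signal)."""


class InsufficientInstrumentsError(CortMRError):
    """An estimator or diagnostic needs more instruments than supplied."""

    def __init__(self, needed: int, got: int, what: str = "estimator"):
        self.needed = needed
        self.got = got
        self.what = what
        super().__init__(f"{what} requires >= {needed} instruments, got {got}")


class PressoNotApplicableError(InsufficientInstrumentsError):
    """MR-PRESSO needs at least four instruments."""

    def __init__(self, got: int):
        super().__init__(4, got, "MR-PRESSO")
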