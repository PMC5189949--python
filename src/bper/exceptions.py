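"""Exception hierarchy for the bper package."""


class BperError(Exception):
    """Base class for all bper-specific errors."""


class PanelParseError(BperError):
    """A panel / pileup / marker file could not be parsed."""


class PileupValidationError(BperError):
    """A pileup table violates its invariants (e.g. counts exceed depth)."""


class ConsistencyError(BperError):
    """Two objects that must share a panel / assay disagree."""


class CalibrationError(BperError):
    """Background calibration or limit-of-blank estimation is impossible."""


class ModelLookupError(BperError):
    """A (position, alteration) pair is absent from a background model."""


class MaskedPositionError(ModelLookupError):
    """The queried panel position is masked (germline-contaminated controls)."""


class ModelVersionError(BperError):
    """A serialized background model has an incompatible schema version."""


class SaturationError(BperError):
    """All droplets are positive: Poisson occupancy is undefined. Dilute."""


class UndefinedRateError(BperError):
    """A rate was requested over an empty denominator."""
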