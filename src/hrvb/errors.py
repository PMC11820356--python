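"""Exception and warning types shared across the package."""


class ParseError(ValueError):
    """Raised when an input file violates the documented layout."""


class SeriesQualityError(ValueError):
    """Raised when an RR series is too corrupted or too short to use."""


class FlatSignalWarning(UserWarning):
    """Emitted when an ECG trace carries no detectable beats."""


class SpectralFallbackWarning(UserWarning):
    """Emitted when a record is too short for Welch averaging and a
    single-segment periodogram is used instead."""


class TrialExclusionWarning(UserWarning):
    """Emitted when a paced-frequency trial is dropped from RF selection."""


class BoundaryWarning(UserWarning):
    """Emitted when an estimate lands on the edge of its search range."""


class DegenerateSweepWarning(UserWarning):
    """Emitted when a sliding sweep carries no usable amplitude contrast."""


class ClippingWarning(UserWarning):
    """Emitted when simulated intervals hit the physiological clip bounds."""


class ProtocolWarning(UserWarning):
    """Emitted for protocol grids that cannot be honoured exactly."""
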