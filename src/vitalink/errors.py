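"""Exception hierarchy shared across the package."""


class VitalinkError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VitalinkError, ValueError):
    """A parameter violates its documented domain (e.g. unattainable SpO2)."""


class InsufficientSignalError(VitalinkError):
    """Not enough pulsatile activity to estimate a vital sign."""


class InvalidSignalError(VitalinkError):
    """Signal violates a physical invariant (e.g. non-positive DC level)."""


class UndefinedRatioError(VitalinkError):
    """Ratio of ratios undefined (zero infrared AC amplitude)."""


class InvalidKeyError(VitalinkError, ValueError):
    """Key or IV has the wrong length or identifier."""


class AuthenticationError(VitalinkError):
    """Decryption failed: wrong key, corrupted ciphertext or bad padding.

    Deliberately coarse: a wrong key and a corrupted payload are
    indistinguishable to the receiver, and no partial record is ever
    returned.
    """


class PayloadFormatError(VitalinkError):
    """Payload is structurally malformed (bad Base64, bad block length)."""


class InsufficientDataError(VitalinkError):
    """Too few paired readings for the requested statistic."""


class DegenerateFitError(VitalinkError):
    """Regression input has zero variance."""


class CorruptedFixtureError(VitalinkError):
    """A packaged reference table failed its integrity check."""


class StageError(VitalinkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
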