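"""Exception types shared across the package."""


class AerolocError(Exception):
    """Base class for package errors."""


class InvalidParameterError(AerolocError, ValueError):
    """A numeric argument violates its precondition (sign, range, band)."""


class LookupMicError(AerolocError, KeyError):
    """A microphone id is not present in the array layout."""


class TruncationError(AerolocError, ValueError):
    """A requested audio segment extends beyond the recording."""


class UndefinedCorrelationError(AerolocError, ValueError):
    """Cross-correlation of an all-zero segment has no defined peak."""


class InfeasibleLagError(AerolocError, ValueError):
    """A range difference exceeds the microphone-pair separation.

    Carries the offending pair so diagnostics can name it.
    """

    def __init__(self, mic_i: str, mic_j: str, delta: float, separation: float):
        self.pair = (mic_i, mic_j)
        self.delta = delta
        self.separation = separation
        super().__init__(
            f"range difference {delta:.4f} m for pair ({mic_i}, {mic_j}) exceeds "
            f"their separation {separation:.4f} m: no hyperboloid exists"
        )


class EmptySummaryError(AerolocError, ValueError):
    """Error statistics requested for an empty set of paired retrievals."""
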