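"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class NotAnActionPotentialError(ValueError):
    """A voltage trace contains no discernible upstroke."""


class TruncatedTraceError(ValueError):
    """A voltage trace ends before 90% repolarisation is reached."""


class CoverageError(ValueError):
    """The achievable APD range does not cover the requested bounds."""

    def __init__(self, requested, achievable):
        self.requested = tuple(requested)
        self.achievable = tuple(achievable)
        super().__init__(
            f"requested APD bounds {self.requested} ms not covered by "
            f"achievable range {self.achievable} ms"
        )


class NumericalInstabilityError(RuntimeError):
    """An integrator produced a non-finite or runaway state."""

    def __init__(self, message, beat=None, step=None):
        self.beat = beat
        self.step = step
        super().__init__(message)


class CalibrationError(RuntimeError):
    """Conductivity calibration failed to bracket or converge."""


class DegenerateSignalError(ValueError):
    """A signal required for normalisation or detection is flat."""


class SingularKernelError(ValueError):
    """An electrode lies inside (or on) a mesh element."""
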