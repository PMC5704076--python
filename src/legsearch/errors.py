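"""Exception types used across the package."""


class LegsearchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LegsearchError):
    """Invalid model configuration (unknown unit label, bad parameter value)."""


class NumericalError(LegsearchError):
    """Integration produced a non-finite state; message names the offending unit."""


class AnalysisError(LegsearchError):
    """A trace does not satisfy the preconditions of an analysis operation."""


class ProtocolError(LegsearchError):
    """The perturbation protocol could not be carried out as configured."""


class NoContactError(ProtocolError):
    """The leg tip never reached the obstacle; message reports the achieved range."""

    def __init__(self, po: float, alpha_min: float, alpha_max: float):
        self.po = po
        self.alpha_min = alpha_min
        self.alpha_max = alpha_max
        super().__init__(
            f"obstacle at PO={po:.1f} deg was never hit on a downward swing; "
            f"alpha stayed in [{alpha_min:.1f}, {alpha_max:.1f}] deg"
        )


class TraceParseError(LegsearchError):
    """A trace file could not be parsed; message carries the line number."""
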