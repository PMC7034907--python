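"""Exception hierarchy."""


class NatronidError(Exception):
    """Base class for all package errors."""


class FormulaError(NatronidError):
    """Malformed or unresolvable chemical formula."""


class EnergyRangeError(NatronidError):
    """Requested photon energy lies outside the tabulated grid (no extrapolation)."""


class NoRootError(NatronidError):
    """Measured attenuation is not attainable by the reference material on the bracket.

    Carries the attainable interval so callers can report it.
    """

    def __init__(self, message, mu_min=None, mu_max=None):
        super().__init__(message)
        self.mu_min = mu_min
        self.mu_max = mu_max


class DegenerateSpectrumError(NatronidError):
    """Filter stack is effectively opaque: the detected spectrum has zero weight."""


class PhantomSpecError(NatronidError):
    """Invalid phantom specification (e.g. a primitive extends outside the grid)."""


class ConfigError(NatronidError):
    """Invalid or unresolvable pipeline configuration."""
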