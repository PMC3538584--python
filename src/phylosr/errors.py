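"""Exception types shared across the package."""


class PhyloSRError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PhyloSRError, ValueError):
    """A model parameter violates its domain (e.g. ti-tv ratio R < 1/2)."""


class InvalidInputError(PhyloSRError, ValueError):
    """Malformed user input (sequences, trees, matrices, config)."""


class SaturationError(PhyloSRError, ArithmeticError):
    """Observed mismatch frequencies fall outside the domain of a
    distance formula's logarithms, so the distance is undefined.

    Attributes
    ----------
    bound : str
        Which domain bound failed (e.g. ``"1-4p_beta"``).
    """

    def __init__(self, message: str, bound: str = ""):
        super().__init__(message)
        self.bound = bound


class NumericalError(PhyloSRError, RuntimeError):
    """An iterative numerical routine failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
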