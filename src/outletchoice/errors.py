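"""Exception types shared across the package."""


class OutletChoiceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OutletChoiceError):
    """A configuration object or file is invalid."""


class DataError(OutletChoiceError):
    """Input tables violate a structural precondition (missing ids, bad domains)."""


class ConvergenceError(OutletChoiceError):
    """An optimizer failed to reach the required gradient tolerance."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SeparationError(OutletChoiceError):
    """Perfect separation: a covariate perfectly predicts an outcome category."""


class IdentificationError(OutletChoiceError):
    """A parameter is not identified (constant within choice sets, rank deficiency,
    or a distance coefficient too close to zero to form willingness-to-travel ratios)."""
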