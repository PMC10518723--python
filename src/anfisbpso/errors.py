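"""Exception types shared across the package."""


class AnfisBpsoError(Exception):
    """Base class for package-specific failures."""


class EmptyDatasetError(AnfisBpsoError):
    """Raised when cleaning or selection leaves no usable data."""


class ConstantColumnError(AnfisBpsoError):
    """Raised when a column to be normalized has max == min."""


class ZeroVarianceFeatureError(AnfisBpsoError):
    """Raised when a Pearson correlation is undefined for a feature."""


class EmptySelectionError(AnfisBpsoError):
    """Raised when no feature survives the p-value/correlation filter."""


class RuleExplosionError(AnfisBpsoError):
    """Raised when the grid-partition rule count exceeds the configured cap."""


class DegenerateActivationError(AnfisBpsoError):
    """Raised when every unmasked rule has zero firing strength."""


class ParameterError(AnfisBpsoError):
    """Raised for invalid membership-function or model parameters."""
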