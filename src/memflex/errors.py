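"""Exception hierarchy shared across the package."""


class MemflexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MemflexError):
    """Invalid or incomplete configuration (selectors, paths, parameters)."""


class EmptyInputError(MemflexError):
    """An input trajectory or sample set contained no usable data."""


class DegenerateBilayerError(MemflexError):
    """Leaflet assignment failed: all lipids fell on one side of the midplane."""


class NonSquareBoxError(MemflexError):
    """Spectral analysis requires a square lateral cell (L_x == L_y)."""


class FitError(MemflexError):
    """A least-squares fit failed to converge or was degenerate."""


class IllConditionedError(MemflexError):
    """A matrix inverse exceeded the conditioning threshold."""


class DegenerateLipidError(MemflexError):
    """A lipid produced a zero-length director or coincident pair."""


class ParameterError(MemflexError):
    """Synthetic-generator parameters are internally inconsistent."""
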