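"""Exception hierarchy shared across the package."""


class ChemocalError(Exception):
    """Base class for all chemocal errors."""


class FormatError(ChemocalError):
    """A file could not be parsed in the declared format."""


class DataError(ChemocalError):
    """Parsed data violate a structural invariant (e.g. duplicate grid points)."""


class SelectionError(ChemocalError):
    """An interval selection matched no grid points."""


class DegenerateSpectrumError(ChemocalError):
    """A pretreatment hit a spectrum it cannot normalize (zero variance / zero area)."""


class GridSpacingError(ChemocalError):
    """An operation requiring an evenly spaced wavenumber grid got an uneven one."""


class ParameterError(ChemocalError):
    """An operation parameter is out of its valid range."""


class DesignError(ChemocalError):
    """A sampling or calibration design cannot be satisfied by the data."""


class RankError(ChemocalError):
    """More latent factors requested than the data can support."""


class CompatibilityError(ChemocalError):
    """A model and a spectrum set do not share grid / intervals / pretreatment."""


class QuantitationError(ChemocalError):
    """Reference-method back-calculation produced a physically impossible value."""
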