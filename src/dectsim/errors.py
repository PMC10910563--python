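"""Exception types shared across the package."""


class DectsimError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(DectsimError, ValueError):
    """Malformed attenuation/spectrum table (names the offending row)."""


class ParameterError(DectsimError, ValueError):
    """Parameter outside its documented domain."""


class EnergyRangeError(DectsimError, ValueError):
    """Energy query outside the tabulated range."""


class DegenerateInputError(DectsimError, ValueError):
    """Input is formally valid but physically degenerate (e.g. zero dose)."""


class GeometryError(DectsimError, ValueError):
    """Sinogram/geometry mismatch or unsupported acquisition geometry."""


class NormalizationError(DectsimError, ValueError):
    """A spectrum was used where a dose-normalized spectrum is required."""
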