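"""Exception hierarchy shared across the pipeline."""


class CavimapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CavimapError):
    """Input data violate a precondition (NaNs, all-zero waveform, empty sequence)."""


class AliasingError(InvalidInputError):
    """Sampling rate too low for the requested analysis band."""


class ConfigurationError(CavimapError):
    """A parameter object is internally inconsistent."""


class IncompatibleGridsError(CavimapError):
    """Voxelwise arithmetic attempted between volumes on different grids."""


class DegenerateInputError(CavimapError):
    """Data technically valid but carrying no usable information (e.g. all voxels invalid)."""


class OffSurfaceError(CavimapError):
    """A query point is too far from the requested mask surface."""


class MissedSkullError(CavimapError):
    """A trajectory does not intersect the skull mask."""
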