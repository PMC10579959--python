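"""Exception hierarchy for atrialign."""


class AtrialignError(Exception):
    """Base class for all package-specific errors."""


class SurfaceParseError(AtrialignError):
    """A surface file could not be parsed (malformed line, bad token, ...)."""


class SurfaceWriteError(AtrialignError):
    """A surface could not be written (empty surface, unsupported format, ...)."""


class DegenerateGeometryError(AtrialignError):
    """Geometry too degenerate for the requested operation (collinear
    neighbourhoods, coincident points, zero spacing, ...)."""


class RegistrationError(AtrialignError):
    """Base class for registration failures."""


class NonOverlappingCloudsError(RegistrationError):
    """Too few correspondences survived outlier rejection."""


class DegenerateNormalsError(RegistrationError):
    """The point-to-plane normal system is rank deficient (e.g. all normals
    parallel): some rigid degrees of freedom are unconstrained."""


class RemeshError(AtrialignError):
    """Isotropic remeshing could not reach the requested spacing uniformity."""


class PhantomError(AtrialignError):
    """Phantom parameters are geometrically impossible or acquisition
    simulation removed too many points."""


class ConfigError(AtrialignError):
    """Invalid or unknown configuration keys/values."""
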