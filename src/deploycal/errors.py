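"""Exception hierarchy shared across the package."""


class DeploycalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DeploycalError):
    """A cohort table is missing a required column or has a malformed value."""


class ReferentialError(DeploycalError):
    """A cross-reference (e.g. a targeted core's lesion_id) does not resolve."""


class ConfigError(DeploycalError, ValueError):
    """An invalid generator or run configuration."""


class DomainError(DeploycalError, ValueError):
    """A scalar argument outside its documented domain."""


class DegenerateInputError(DeploycalError, ValueError):
    """Input on which the requested statistic is undefined."""


class GeometryError(DeploycalError, ValueError):
    """Voxel-grid shapes or coordinates are inconsistent."""


class WindowError(DeploycalError, ValueError):
    """Not enough examinations to fill a look-back window."""


class AlignmentError(DeploycalError, ValueError):
    """Two detection vectors do not describe the same units."""


class MissingDataError(DeploycalError):
    """A score or voxel map required for the requested call is absent."""
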