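"""Exception types shared across the package."""


class ArchoposeError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(ArchoposeError):
    """Raised when a mesh file violates the triangles-only OBJ contract."""


class PatchError(ArchoposeError):
    """Raised when a surface-patch selection is invalid for its mesh."""


class DegenerateGeometryError(ArchoposeError):
    """Raised when input geometry cannot support the requested fit or
    construction (coplanar sphere points, parallel principal vectors, ...)."""


class ConvergenceError(ArchoposeError):
    """Raised when an iterative fit fails to converge within its budget."""


class ConfigError(ArchoposeError):
    """Raised for invalid or inconsistent run configuration."""
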