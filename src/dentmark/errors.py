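"""Exception hierarchy shared across the package."""


class DentmarkError(Exception):
    """Base class for all package-specific errors."""


class MeshParseError(DentmarkError):
    """STL file is missing, empty, or does not parse."""


class EmptyMeshError(DentmarkError):
    """Mesh contains no triangles after cleanup."""


class DegenerateGeometryError(DentmarkError):
    """Geometry too degenerate for the requested operation
    (rank-deficient covariance, collinear points, too few samples)."""


class RefinementSkipped(DentmarkError):
    """Occlusal refinement could not run; the prior frame should be kept."""


class ConfigError(DentmarkError):
    """Invalid pipeline configuration (unknown key, out-of-bounds value,
    non-monotone score mapping)."""


class StageError(DentmarkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
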