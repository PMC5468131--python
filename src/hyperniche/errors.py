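"""Exception types shared across the package."""


class HypernicheError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HypernicheError):
    """Invalid configuration (bad world recipe, missing paths, out-of-range parameters)."""


class GridMismatchError(HypernicheError):
    """Raster layers do not share grid shape / georeference."""


class InfeasibleSamplingError(HypernicheError):
    """Fewer qualifying cells than requested samples.

    Carries ``available`` so callers can report how many cells satisfied
    the constraint.
    """

    def __init__(self, requested: int, available: int, what: str = "cells"):
        self.requested = requested
        self.available = available
        super().__init__(
            f"requested {requested} {what} but only {available} qualify"
        )


class DegenerateGeometryError(HypernicheError):
    """Point cloud is rank-deficient; a convex polytope would collapse."""

    def __init__(self, rank: int, dim: int):
        self.rank = rank
        self.dim = dim
        super().__init__(
            f"point cloud has affine rank {rank} < dimension {dim}; "
            "convex-polytope volume is undefined"
        )


class ZeroVarianceError(HypernicheError):
    """A variable (or group sample) has zero variance where spread is required."""
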