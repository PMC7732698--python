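"""Exception hierarchy.

Every error raised deliberately by fabdyn derives from :class:`FabDynError`,
so callers can catch one type at pipeline level and record per-measure
failures without masking genuine bugs.
"""


class FabDynError(Exception):
    """Base class for all fabdyn errors."""


class FormatError(FabDynError):
    """A file could not be parsed in the expected format."""


class EmptyStructureError(FabDynError):
    """A structure source yielded zero usable atoms."""


class TopologyError(FabDynError):
    """Trajectory frames do not match the topology (e.g. atom count)."""


class ValidationError(FabDynError):
    """Invalid parameter or configuration value."""


class EmptySelectionError(FabDynError):
    """A residue selection resolved to no atoms."""


class DegenerateGeometryError(FabDynError):
    """Geometry is degenerate (collinear points, atoms on axis, ...)."""


class SamplingError(FabDynError):
    """A time series violates the uniform-sampling requirements."""


class InsufficientCoreError(FabDynError):
    """Fewer than three reference core positions could be resolved."""


class IllDefinedAxisError(FabDynError):
    """A pseudo-two-fold rotation is too small to define an axis."""


class DegenerateDistributionError(FabDynError):
    """An angle distribution is too narrow to invert (single bin)."""


class InsufficientDataError(FabDynError):
    """Not enough usable bins/samples for a fit."""


class NonParabolicError(FabDynError):
    """A free-energy profile has negative curvature at the fit window."""


class ConstructionError(FabDynError):
    """A synthetic-structure prescription is geometrically infeasible."""


class ComparisonError(FabDynError):
    """Two ensemble reports share no common measures."""
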