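"""Exception hierarchy.

Every error raised by mdligand derives from :class:`MDLigandError`, so
callers (and the CLI) can distinguish analysis failures from programming
errors.
"""


class MDLigandError(Exception):
    """Base class for all mdligand errors."""


class FormatError(MDLigandError):
    """A structure/trajectory/sidecar file is malformed."""


class ParameterError(MDLigandError):
    """A required per-atom parameter (charge, LJ, radius) is missing or invalid."""


class SelectionError(MDLigandError):
    """A selection is empty, overlapping, or cannot be resolved."""


class TrajectoryMismatchError(MDLigandError):
    """Trajectory atom count does not match the topology."""


class EmptyTrajectoryError(MDLigandError):
    """An operation removed every frame (e.g. burn-in longer than the run)."""


class InsufficientDataError(MDLigandError):
    """Too few frames/samples for the requested statistic."""


class GeometryError(MDLigandError):
    """Degenerate geometry (collinear fit atoms, collinear ring, ...)."""


class SyntheticSpecError(MDLigandError):
    """A synthetic-trajectory specification is inconsistent or infeasible."""


class SingularityError(MDLigandError):
    """Coincident atoms in a pairwise energy sum."""


class ConfigError(MDLigandError):
    """Invalid analysis or pipeline configuration."""
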