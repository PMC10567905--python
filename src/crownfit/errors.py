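"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: validation errors -> 2,
geometry / alignment failures -> 3, I/O and format problems -> 4.
"""


class CrownFitError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ValidationError(CrownFitError):
    """Invalid configuration, parameters, or input values."""

    exit_code = 2


class SpecError(ValidationError):
    """A generator or measurement spec violates its invariants."""


class SampleSizeError(ValidationError):
    """Too few observations for the requested statistic."""


class DegenerateVarianceError(ValidationError):
    """Pooled variance is zero while the group means differ."""


class GeometryError(CrownFitError):
    """Geometric precondition violated (e.g. curve too far from mesh)."""

    exit_code = 3


class OrderingError(GeometryError):
    """Margin landmarks do not form an orderable closed ring."""


class RankError(GeometryError):
    """Point configuration is rank-deficient (collinear / coincident)."""


class AlignmentError(GeometryError):
    """Registration failed; carries the last iteration state if any."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class OrientationError(GeometryError):
    """Mesh winding is inconsistent; signed distances are undefined."""


class MeshIOError(CrownFitError):
    """Unreadable or unwritable mesh / landmark file."""

    exit_code = 4


class FormatError(MeshIOError):
    """File exists but cannot be parsed in the requested format."""


class ContentError(MeshIOError):
    """File parsed but its content is unusable (e.g. empty mesh)."""
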