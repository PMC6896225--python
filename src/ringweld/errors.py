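"""Exception hierarchy.

Every error raised by ringweld derives from :class:`RingweldError` so the CLI
can map domain failures to exit code 1 while genuine bugs propagate.
"""


class RingweldError(Exception):
    """Base class for all ringweld domain errors."""


class SizeError(RingweldError):
    """Mismatched array/point-set sizes."""


class GeometryError(RingweldError):
    """Degenerate or invalid geometry (collinear points, zero axis, ...)."""


class FormatError(RingweldError):
    """Unparsable or unsupported file content."""


class ClassificationError(RingweldError):
    """Unknown residue/atom name with no mapping entry."""


class OrderError(RingweldError):
    """Non-monotone frame times."""


class SpecError(RingweldError):
    """Invalid generator/protocol specification."""


class TopologyError(RingweldError):
    """Bead-table inconsistency (missing head bead, id mismatch, ...)."""


class DivergenceError(RingweldError):
    """Non-finite coordinates produced by the integrator."""


class SelectionError(RingweldError):
    """Empty bead selection where a non-empty one is required."""


class DegenerateInputError(RingweldError):
    """Input with no usable signal (flat map, empty population, ...)."""


class MaskError(RingweldError):
    """Mask with too few voxels or incompatible lattice."""


class ScriptError(RingweldError):
    """Contradictory scripted-trajectory events."""


class ConfigError(RingweldError):
    """Unknown or ill-typed configuration key."""
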