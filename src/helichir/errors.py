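"""Exception hierarchy.

Every error raised by this package derives from :class:`HelichirError`, so
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class HelichirError(ValueError):
    """Base class for all domain errors."""


class InvalidInputError(HelichirError):
    """A numeric input is non-finite or otherwise malformed."""


class UnitMismatchError(HelichirError):
    """Vectors carrying different units were combined in one computation."""


class InsufficientVectorsError(HelichirError):
    """Too few vectors/points for the requested chirality sum."""


class DegenerateNormalizationError(HelichirError):
    """Normalization by a non-positive mean dipole magnitude."""


class TableFormatError(HelichirError):
    """A dipole table file violates the TSV dialect."""


class StructureFormatError(HelichirError):
    """An atomic structure file could not be parsed."""


class MassLookupError(HelichirError):
    """An element symbol could not be resolved to a standard atomic weight."""


class EmptyTraceError(HelichirError):
    """No C-alpha atoms found for the requested chain."""


class PartitionError(HelichirError):
    """Molecule partitioning failed or produced ambiguous groups."""


class MissingChargeError(HelichirError):
    """Point-charge dipole requested but some atoms carry no charge."""


class DegenerateFitError(HelichirError):
    """Helix-parameter fit on degenerate geometry (collinear or planar points)."""
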