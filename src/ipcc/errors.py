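"""Exception hierarchy.

Every error raised by this package derives from :class:`IpccError`, so
callers (and the command-line wrapper) can distinguish data problems from
programming errors with a single ``except`` clause.
"""


class IpccError(Exception):
    """Base class for all errors raised by ipcc."""


# --- core ---------------------------------------------------------------

class ZeroVarianceSample(IpccError):
    """A sample's expression profile is constant; Pearson correlation is
    undefined (division by a zero norm)."""


class ZeroVarianceRow(IpccError):
    """A row of an intermediate correlation-feature matrix is constant."""


class TooFewGenes(IpccError):
    """Fewer than two genes: a per-sample correlation needs >= 2 values."""


class DegenerateIteration(IpccError):
    """The feature matrix is too small to iterate (m = 2 collapses every
    row to two entries and the row-correlation map degenerates)."""


class UnknownKernel(IpccError):
    """Correlation kernel name not recognised."""


# --- batch --------------------------------------------------------------

class UnlabeledSample(IpccError):
    """A sample has no batch assignment."""


class ShapeMismatch(IpccError):
    """Matrix shapes do not agree."""


# --- simulate -----------------------------------------------------------

class InvalidSpec(IpccError):
    """Simulation parameters are inconsistent or non-positive."""


class UnknownKind(IpccError):
    """Null-data distribution name not recognised."""


class UnknownToy(IpccError):
    """Toy fixture id must be 1, 2 or 3."""


# --- evaluate -----------------------------------------------------------

class AllGenesFiltered(IpccError):
    """Preprocessing removed every gene."""


class DegenerateClass(IpccError):
    """A class has too few samples for the requested operation."""


class KLargerThanM(IpccError):
    """More clusters requested than samples available."""


class SampleMismatch(IpccError):
    """Predicted and true labelings cover different samples."""


class SingleClass(IpccError):
    """Inter-class statistics need at least two classes."""


class InsufficientReplicates(IpccError):
    """A two-sample test needs at least two values per group."""


# --- io -----------------------------------------------------------------

class ParseError(IpccError):
    """Malformed input file."""


class DuplicateSampleID(IpccError):
    """Sample identifiers in a header are not unique."""


class UnknownSample(IpccError):
    """A label file references a sample absent from the matrix (or vice
    versa, for supervised operations)."""
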