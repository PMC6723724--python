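"""Named exceptions raised across the package."""


class MofuzzError(Exception):
    """Base class for all package-specific errors."""


class NegativeEntryError(MofuzzError):
    """A count matrix contains a negative value."""


class DuplicateIdentifierError(MofuzzError):
    """Gene or cell identifiers are not unique."""


class DimensionMismatchError(MofuzzError):
    """Matrix shape disagrees with the identifier lists."""


class MissingFileError(MofuzzError):
    """An input file (or a required sidecar) does not exist."""


class EmptyResultError(MofuzzError):
    """A filter removed every gene or every cell."""


class ZeroDepthError(MofuzzError):
    """A cell has zero total counts where positive depth is required."""


class TooFewSlopesError(MofuzzError):
    """Fewer than two finite slopes were supplied to a mode estimate."""


class DegenerateColumnError(MofuzzError):
    """A decision-matrix column cannot be normalized (all-zero or constant)."""


class DegeneratePartitionError(MofuzzError):
    """A fuzzy partition carries no information (all silhouette weights zero)."""


class GroupTooSmallError(MofuzzError):
    """A contrast group has fewer cells than the test requires."""
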