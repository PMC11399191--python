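"""Exception hierarchy shared across the pipeline stages."""


class BpeQuantError(Exception):
    """Base class for all bpequant errors."""


class InvalidSpecError(BpeQuantError, ValueError):
    """A simulation or run specification violates its invariants."""


class GridMismatchError(BpeQuantError, ValueError):
    """Volumes that must share one voxel grid do not."""


class PhaseCountError(BpeQuantError, ValueError):
    """A DCE series has fewer than two phases."""


class PhaseIndexError(BpeQuantError, ValueError):
    """An early/delayed phase index is out of range or inconsistent."""


class EmptyRegionError(BpeQuantError, ValueError):
    """A breast or FGT mask contains no voxels."""


class InsufficientDataError(BpeQuantError, ValueError):
    """Fewer valid voxels than phases; the decomposition is underdetermined."""


class DegenerateDataError(BpeQuantError, ValueError):
    """All-zero voxel matrix or degenerate eigenvector."""


class DegenerateTableError(BpeQuantError, ValueError):
    """Contingency table collapses below 2x2 after dropping empty rows/columns."""


class CollinearityError(BpeQuantError, ValueError):
    """Rank-deficient regression design; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


class EmptyGroupError(BpeQuantError, ValueError):
    """A comparison group is empty (possibly after stratification)."""


class MatchPreconditionError(BpeQuantError, ValueError):
    """Propensity matching called with treated group larger than control."""
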