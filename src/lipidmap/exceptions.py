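"""Exception hierarchy.

Every error raised by lipidmap derives from :class:`LipidmapError` so callers
can catch the package's failures without masking programming errors.
"""


class LipidmapError(Exception):
    """Base class for all lipidmap errors."""


class InvalidSpecError(LipidmapError):
    """A membrane/site/truth specification violates its invariants."""


class PackingError(LipidmapError):
    """Lipid placement failed after bounded retries."""

    def __init__(self, leaflet: str, message: str):
        super().__init__(message)
        self.leaflet = leaflet


class StabilityError(LipidmapError):
    """Integration step too large for the narrowest planted site."""


class FormatError(LipidmapError):
    """Unparseable coordinate/trajectory file."""

    def __init__(self, message: str, line: int | None = None, frame: int | None = None):
        super().__init__(message)
        self.line = line
        self.frame = frame


class StructuralMismatchError(LipidmapError):
    """Bead count differs between coordinate and trajectory files."""


class ResolutionError(LipidmapError):
    """Requested stride finer than the native frame spacing."""


class GeometryError(LipidmapError):
    """Degenerate box, axis outside grid, or empty spatial intersection."""


class SelectionError(LipidmapError):
    """A selector matched nothing or used an unknown category."""


class EmptySelectionError(SelectionError):
    """A density/contact selection matched zero beads or molecules."""


class AnnotationError(LipidmapError):
    """Topology annotation is incomplete (e.g. lipid without anchor bead)."""


class AlignmentError(LipidmapError):
    """Residue indexing inconsistent across repeats."""


class CommensurabilityError(LipidmapError):
    """Grids do not share origin/spacing/shape."""


class NotFoundError(LipidmapError):
    """Requested ligand/residue absent from a structure."""

    def __init__(self, message: str, available: list[str] | None = None):
        super().__init__(message)
        self.available = available or []


class MappingError(LipidmapError):
    """No table residue maps onto the target structure."""


class UndefinedMetricError(LipidmapError):
    """Metric undefined for the input (e.g. all-zero grid)."""


class ConfigError(LipidmapError):
    """Run configuration failed validation."""

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = keys or []


class BudgetExceededError(LipidmapError):
    """A Monte-Carlo estimate did not converge within its step budget."""

    def __init__(self, message: str, partial_mean: float, partial_sem: float, n_done: int):
        super().__init__(message)
        self.partial_mean = partial_mean
        self.partial_sem = partial_sem
        self.n_done = n_done
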