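"""Exception hierarchy for the flatfold pipeline."""


class FlatfoldError(Exception):
    """Base class for all flatfold errors."""


class EmptyStructureError(FlatfoldError):
    """A structure file contained no usable Calpha atoms."""


class EmptyDomainError(FlatfoldError):
    """A domain extraction matched no residues."""


class GeometryError(FlatfoldError):
    """Degenerate geometry (coincident points, rank-deficient point sets)."""


class UnsupportedTopologyError(FlatfoldError):
    """A beta-sheet adjacency graph is not a simple path (barrel / bifurcation)."""

    def __init__(self, message: str, strands: list[str] | None = None):
        super().__init__(message)
        self.strands = list(strands or [])


class GenerationError(FlatfoldError):
    """Synthetic-structure generation could not satisfy its geometric constraints."""
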