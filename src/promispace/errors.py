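"""Exception hierarchy.

All package-specific failures derive from :class:`PromispaceError` so callers
can catch one base class at CLI or pipeline boundaries.
"""


class PromispaceError(Exception):
    """Base class for all promispace errors."""


class MalformedInputError(PromispaceError):
    """An input file or row violates the declared dialect."""


class StructureError(PromispaceError):
    """A SMILES/structure could not be parsed or reassembled."""

    def __init__(self, message: str, compound_id: str | None = None):
        self.compound_id = compound_id
        if compound_id is not None:
            message = f"{message} (compound {compound_id!r})"
        super().__init__(message)


class EmptyDatasetError(PromispaceError):
    """Curation or filtering produced an empty result."""


class MissingProfileError(PromispaceError):
    """A compound referenced by an MMP has no target profile."""


class EmptySubmatrixError(PromispaceError):
    """Submatrix extraction removed every real cell."""


class CellCollisionError(PromispaceError):
    """Two distinct compounds mapped to one matrix cell."""
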