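"""Exception hierarchy shared by all viromine modules."""


class ViromineError(Exception):
    """Base class for all errors raised by viromine."""


class FormatError(ViromineError):
    """A file violates its declared format.

    Carries the 1-based line number of the first offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyInputError(ViromineError):
    """An input file or collection that must be non-empty is empty."""


class DuplicateIdError(ViromineError):
    """Two records in one collection share an identifier."""


class ParameterError(ViromineError):
    """A parameter value violates its contract."""


class MoleculeTypeError(ViromineError, TypeError):
    """A nucleotide operation received a protein record, or vice versa."""


class UndefinedValueError(ViromineError):
    """The requested quantity is mathematically undefined for this input
    (e.g. G+C content of an all-N sequence, abundance with zero counts,
    SG of a genome with zero self-score)."""


class ContractError(ViromineError):
    """An internal data-structure invariant was violated (e.g. a
    non-symmetric similarity matrix passed to the tree builder)."""
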