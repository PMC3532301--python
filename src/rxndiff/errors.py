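"""Exception hierarchy.

Everything raised on purpose derives from :class:`RxndiffError`, so callers
(and the CLI) can distinguish domain failures from genuine bugs.
"""


class RxndiffError(Exception):
    """Base class for all errors raised by rxndiff."""


class StructureParseError(RxndiffError):
    """A structure record (SMILES, molfile) could not be parsed.

    Carries the offending record (truncated) so batch loaders can report it.
    """

    def __init__(self, record: str, fmt: str, detail: str = ""):
        self.record = record
        self.fmt = fmt
        snippet = record if len(record) <= 120 else record[:117] + "..."
        msg = f"cannot parse {fmt} record {snippet!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class FragmentLengthError(RxndiffError):
    """Requested path length outside the supported 0..6 bond range."""


class FragmentSyntaxError(RxndiffError):
    """A fragment string does not alternate atom and bond symbols."""


class DialectMismatchError(RxndiffError):
    """Two fingerprints were built under incomparable dialects."""


class MissingStructureError(RxndiffError):
    """A reaction references a compound whose structure is declared absent."""

    def __init__(self, compound_id: str):
        self.compound_id = compound_id
        super().__init__(f"no structure available for compound {compound_id!r}")


class UnknownCompoundError(RxndiffError):
    """A reaction references a compound id absent from the compound table.

    Distinct from :class:`MissingStructureError`: the id is not even declared,
    which points at a data-integrity problem rather than a known gap.
    """

    def __init__(self, compound_id: str):
        self.compound_id = compound_id
        super().__init__(f"compound id {compound_id!r} not present in the compound table")


class CoefficientError(RxndiffError):
    """A stoichiometric coefficient is symbolic or non-positive where an
    integer is required."""


class EquationParseError(RxndiffError):
    """An equation string is malformed; carries the character position."""

    def __init__(self, text: str, position: int, detail: str):
        self.text = text
        self.position = position
        super().__init__(f"bad equation at position {position}: {detail} in {text!r}")


class ECLabelError(RxndiffError):
    """An EC label string violates the dotted-hierarchy grammar."""


class ZeroFingerprintError(RxndiffError):
    """A reaction with an all-zero difference fingerprint reached an
    operation that cannot use it; run filter_dataset first."""


class ClassifierError(RxndiffError):
    """Invalid classifier input (empty training set, unusable labels...)."""


class TemplateError(RxndiffError):
    """A transformation template could not be applied as requested."""
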