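"""Exception types shared across the package."""


class ProteoquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ProteoquantError):
    """Malformed input file: missing column, bad character, non-numeric cell."""


class DuplicateEntryError(ProteoquantError):
    """Duplicate identifier where uniqueness is required (FASTA header, map tag)."""


class UnknownProteinError(ProteoquantError):
    """A PSM references a protein absent from the database."""


class UnquantifiablePSMError(ProteoquantError):
    """A PSM cannot enter ratio space (missing or non-positive reporter intensity)."""
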