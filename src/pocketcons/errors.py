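"""Exception hierarchy shared across the package."""


class PocketconsError(Exception):
    """Base class for all errors raised by pocketcons."""


class ParseError(PocketconsError):
    """An input file could not be parsed (PDB, pocket file, FASTA, PROSITE)."""


class ValidationError(PocketconsError):
    """Inputs parsed but are mutually inconsistent or violate a contract."""
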