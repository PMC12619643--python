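"""Exception hierarchy; every stage raises a subclass of PaeDomainsError."""


class PaeDomainsError(Exception):
    """Base class for all errors raised by this package."""


class PaeParseError(PaeDomainsError):
    """Malformed PAE JSON (syntax error; byte offset is named when known)."""


class PaeShapeError(PaeDomainsError):
    """PAE matrix is ragged, non-square, or too small."""


class PaeDomainError(PaeDomainsError):
    """PAE values outside the valid domain (negative entries)."""


class DialectError(PaeDomainsError):
    """JSON does not match any supported PAE dialect."""


class StructureFormatError(PaeDomainsError):
    """Structure file could not be read as PDB or mmCIF."""


class EmptyStructureError(PaeDomainsError):
    """Structure contains no polymer residues."""


class ReconciliationError(PaeDomainsError):
    """PAE matrix size and residue table length disagree."""


class DegenerateInputError(PaeDomainsError):
    """Input too small for the operation (e.g. a 1-residue network)."""


class ConfigurationError(PaeDomainsError):
    """Invalid parameter combination (e.g. unknown clustering objective)."""


class ChoppingParseError(PaeDomainsError):
    """Malformed domain chopping string; names the offending token."""


class GenerationError(PaeDomainsError):
    """Invalid synthetic-fixture specification."""
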