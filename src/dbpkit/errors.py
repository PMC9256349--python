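"""Exception hierarchy shared across the package."""


class DbpkitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DbpkitError):
    """A file could not be parsed (malformed FASTA, PSSM, or matrix file)."""


class ShapeError(DbpkitError):
    """A matrix or table has a shape inconsistent with its bound sequence."""


class ConsistencyError(DbpkitError):
    """Two inputs that must agree (e.g. PSSM residue column vs sequence) do not."""


class ConfigError(DbpkitError):
    """Invalid configuration or operation parameters."""
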