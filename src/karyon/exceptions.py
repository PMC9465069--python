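"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`KaryonError`,
so callers (and the CLI) can separate data problems from genuine bugs.
"""


class KaryonError(Exception):
    """Base class for all errors raised by karyon."""


class GFFParseError(KaryonError):
    """A GFF line could not be parsed; the message names the line number."""


class DuplicateIdError(KaryonError):
    """A FASTA file contains duplicate record ids."""


class CoordinateMismatchError(KaryonError):
    """Gene coordinates exceed the contig length (FASTA/GFF disagree)."""


class MissingLengthError(KaryonError):
    """A contig id has no known sequence length."""


class InsufficientGenesError(KaryonError):
    """A contig has fewer than the two genes the features require."""


class SchemaError(KaryonError):
    """A feature matrix does not match the expected column schema."""


class ModelFormatError(KaryonError):
    """A model file is unreadable or corrupt."""


class ModelVersionError(KaryonError):
    """A model file was written with an incompatible schema version."""


class ParameterError(KaryonError, ValueError):
    """An invalid parameter value was supplied."""
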