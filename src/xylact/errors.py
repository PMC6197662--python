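"""Exception hierarchy.

Every error raised by the library derives from :class:`XylactError`, so
callers (and the CLI exit-code mapping) can distinguish input/schema
problems from model/metric problems with two ``except`` clauses.
"""


class XylactError(Exception):
    """Base class for all xylact errors."""


class InputError(XylactError):
    """Bad input data or configuration (CLI exit code 2)."""


class ModelError(XylactError):
    """Model fitting / prediction / metric failure (CLI exit code 3)."""


class DegenerateIndexError(InputError):
    """An amino-acid index table is constant and cannot be standardized."""


class IncompleteTableError(InputError):
    """An index table does not cover all 20 canonical residues."""


class AlphabetError(InputError):
    """A sequence contains a residue outside the canonical 20-letter alphabet."""


class SequenceTooShortError(InputError):
    """Sequence length L does not exceed the correlation depth lambda."""


class NormalizationError(XylactError):
    """The pseudo-composition denominator is non-positive for a sequence."""


class SchemaError(InputError):
    """A tabular input violates the strain-table column contract."""


class FormatError(InputError):
    """A sequence file is malformed (empty record, duplicate id, ...)."""


class AlignmentError(InputError):
    """Feature rows and strain records cannot be matched by accession."""


class ParameterError(InputError):
    """An operation was called with inconsistent parameters (e.g. K > n)."""


class NotFittedError(ModelError):
    """predict was called before fit."""


class MissingReferenceDataError(InputError):
    """A reference artifact (e.g. the published feature matrix) is not available."""
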