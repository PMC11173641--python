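"""Exception hierarchy with stable CLI exit codes.

Validation errors (bad parameters, unknown labels) exit 2, integrity errors
(duplicate accessions, mismatched sample sets) exit 3, and format/IO errors
(missing columns, unreadable files) exit 4.
"""


class AcetoprotError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(AcetoprotError):
    """A parameter or label is outside its documented range."""

    exit_code = 2


class IntegrityError(AcetoprotError):
    """Data violates a structural invariant (e.g. duplicate accession)."""

    exit_code = 3


class FormatError(AcetoprotError):
    """An input file does not match the expected tabular format."""

    exit_code = 4


class ConfigurationError(ValidationError):
    """A grouping or threshold configuration is unusable (e.g. empty group)."""
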