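"""Exception hierarchy shared across the toolkit.

Each class maps to a distinct CLI exit code (see :mod:`oncostump.cli`).
"""


class OncostumpError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OncostumpError):
    """A file or text blob does not conform to its documented dialect."""


class AlignmentError(FormatError):
    """An alignment violates its invariants (e.g. ragged rows)."""


class ParseError(FormatError):
    """Content parsed but is semantically ambiguous (e.g. duplicate keys)."""


class SchemaError(OncostumpError):
    """A tabular input is missing required columns or holds invalid values."""


class ModeError(OncostumpError):
    """SEQ/STR mode mismatch: required structural annotation is absent."""


class ShapeError(OncostumpError):
    """Array width does not match the model or schema expectation."""
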