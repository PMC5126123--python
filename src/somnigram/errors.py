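"""Exception hierarchy shared across the pipeline.

Every module raises subclasses of :class:`SomnigramError` so that the CLI can
map any pipeline failure to a single-line diagnostic and a nonzero exit code.
"""


class SomnigramError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SomnigramError):
    """A file does not parse as the expected format."""


class ConfigError(SomnigramError):
    """Invalid configuration: unknown key, bad label, out-of-range parameter."""


class EmptyInputError(SomnigramError):
    """An input that must be nonempty is empty."""


class ParseError(FormatError):
    """A text file contains cells that cannot be parsed as numbers."""


class AlignmentError(SomnigramError):
    """Two recorded streams share no overlapping time interval."""


class InsufficientDataError(SomnigramError):
    """Not enough data for the requested computation."""


class InputTooShortError(InsufficientDataError):
    """Recording shorter than the longest analysis window."""


class ContractError(SomnigramError):
    """An operation received an object in the wrong processing stage or shape."""


class NumericalError(SomnigramError):
    """A numerical routine produced non-finite values."""
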