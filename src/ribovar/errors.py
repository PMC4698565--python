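"""Exception hierarchy shared across the package."""


class RibovarError(Exception):
    """Base class for all errors raised by this package."""


class InputError(RibovarError):
    """Empty or otherwise unusable input."""


class AlignmentError(RibovarError):
    """Rows of unequal length, or sequences that cannot be compared."""


class AlphabetError(RibovarError):
    """A symbol outside the permitted nucleotide/gap alphabet."""


class LabelFormatError(RibovarError):
    """A clone label that does not match ``<specimen>_#<nn>``."""


class ConsistencyError(RibovarError):
    """Two objects that must describe the same rows do not."""


class ConfigurationError(RibovarError):
    """An invalid mode, threshold or simulation parameter."""


class DegenerateInputError(RibovarError):
    """Input too small for the requested summary (e.g. a 1x1 matrix)."""


class FixtureError(RibovarError):
    """A packaged fixture is inconsistent or was asked for out of range."""
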