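"""Exception hierarchy for emsmap."""


class EmsmapError(Exception):
    """Base class for all emsmap errors."""


class ConfigurationError(EmsmapError, ValueError):
    """Invalid configuration: bad parameter value, missing sample, infeasible layout."""


class FormatError(EmsmapError, ValueError):
    """Malformed input file: missing column, bad AD string, truncated ANN field."""


class ReferenceMismatchError(EmsmapError, ValueError):
    """A variant's REF allele disagrees with the reference sequence."""


class NoSignalError(EmsmapError, RuntimeError):
    """The analysis has nothing to work with (e.g. zero filtered markers)."""
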