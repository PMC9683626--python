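"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (config=2, format=3, data=4).
"""


class LensgexError(Exception):
    """Base class for all package errors."""


class FormatError(LensgexError, ValueError):
    """A file violates the on-disk format contract (duplicates, bad cells, missing markers)."""


class ConfigurationError(LensgexError, ValueError):
    """The run configuration is inconsistent with the data (missing samples, unmapped titles)."""


class DesignError(LensgexError, ValueError):
    """A simulation design is internally inconsistent (class sizes, fractions out of range)."""


class DegenerateInputError(LensgexError, ValueError):
    """Statistics requested on inputs too small to carry them (n < 2 per side)."""


class DataError(LensgexError, ValueError):
    """Runtime data error not covered by the categories above."""
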