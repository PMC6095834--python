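"""Exception hierarchy shared by all poolscreen modules."""


class PoolscreenError(Exception):
    """Base class for all errors raised by poolscreen."""


class ParameterError(PoolscreenError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(PoolscreenError, ValueError):
    """An input file does not conform to the expected tabular format."""


class ValidationError(PoolscreenError, ValueError):
    """Parsed data violates a structural invariant (e.g. missing timepoint)."""


class LibraryError(PoolscreenError, ValueError):
    """The hairpin library is internally inconsistent (e.g. ambiguous barcodes)."""


class NormalizationError(PoolscreenError, ValueError):
    """Size factors cannot be estimated from the given count table."""


class DispersionError(PoolscreenError, ValueError):
    """Dispersion estimation is impossible with the given replicate structure."""
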