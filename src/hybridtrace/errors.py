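"""Exception hierarchy shared across the pipeline stages."""


class HybridtraceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HybridtraceError):
    """Invalid panel/run configuration (unknown sample id, overlapping panels, ...)."""


class VcfParseError(HybridtraceError):
    """Malformed variant input."""


class ArgumentError(HybridtraceError, ValueError):
    """Invalid argument value to an operation."""


class DataError(HybridtraceError):
    """Input data violates a stage precondition (e.g. missing focal genotype)."""


class UnsupportedSiteError(HybridtraceError):
    """Site cannot be represented in the requested output (e.g. indel in a SNP alignment)."""


class UndefinedResultError(HybridtraceError):
    """The requested statistic is undefined on the given input."""
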