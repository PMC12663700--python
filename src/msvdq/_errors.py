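"""Exception hierarchy shared across the package."""


class MsvdqError(Exception):
    """Base class for all package-specific errors."""


class CodebookError(MsvdqError):
    """The codebook violates one of its structural invariants."""


class DatasetError(MsvdqError):
    """The raw dataset is inconsistent with the codebook or empty."""


class ConfigError(MsvdqError):
    """A simulation or pipeline configuration is invalid."""


class ImputationError(MsvdqError):
    """Chained-equations imputation cannot proceed (e.g. a fully missing column)."""


class MetricError(MsvdqError):
    """A distribution-metric precondition failed (lengths, mass, embeddability)."""


class ScopeError(MsvdqError):
    """An analysis scope cannot be evaluated (too few variables/rows)."""
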