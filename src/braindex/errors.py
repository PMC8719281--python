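"""Exception hierarchy shared across the pipeline stages."""


class BraindexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BraindexError, ValueError):
    """Invalid configuration value (e.g. non-positive noise SD)."""


class AlignmentError(BraindexError, ValueError):
    """Tables or vectors that must share an index/name set do not."""


class DegenerateDesignError(BraindexError, ValueError):
    """A regression design matrix is rank deficient (e.g. constant covariate)."""


class InsufficientDataError(BraindexError, ValueError):
    """Too few non-missing observations for the requested operation."""


class AnalysisError(BraindexError, ValueError):
    """A downstream analysis precondition failed (e.g. empty group)."""
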