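"""Exception hierarchy. Every user-facing failure derives from WfsmoothError
so the CLI can catch one type and exit nonzero with a one-line diagnostic."""


class WfsmoothError(Exception):
    """Base class for all wfsmooth errors."""


class FormatError(WfsmoothError):
    """Malformed interchange file (bad header, non-contiguous frame index...)."""


class VocabularyError(WfsmoothError):
    """A label not present in the supplied vocabulary, or an invalid vocabulary."""


class PairingError(WfsmoothError):
    """Ground truth and prediction cannot be paired (length/vocabulary mismatch)."""


class ConfigurationError(WfsmoothError):
    """Invalid smoother, simulation or run configuration."""


class EstimationError(WfsmoothError):
    """HMM estimation failed (e.g. empty training set)."""


class DecodingError(WfsmoothError):
    """No admissible state path exists for an observation sequence."""


class AggregationError(WfsmoothError):
    """Cross-fold aggregation requested on fewer than two folds."""
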