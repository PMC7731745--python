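"""Exception types shared across the pipeline."""


class MethylpairError(Exception):
    """Base class for pipeline errors."""


class ConfigError(MethylpairError, ValueError):
    """Invalid configuration value or combination."""


class SizingError(ConfigError):
    """A simulated chromosome is too small to host the requested layout."""


class PlacementError(MethylpairError, RuntimeError):
    """Requested features cannot be placed disjointly."""


class ReportParseError(MethylpairError, ValueError):
    """Malformed per-CpG count report; message names the offending line."""


class EstimationError(MethylpairError, RuntimeError):
    """A statistical estimator has no usable input (e.g. no all-positive site)."""
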