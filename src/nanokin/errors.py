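"""Exception hierarchy and warnings shared across the pipeline stages."""


class NanokinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NanokinError):
    """A scheme, noise model, acquisition setting or run config is invalid."""


class DataIntegrityError(NanokinError):
    """A file on disk is inconsistent with its metadata (truncated, corrupt)."""


class InsufficientDataError(NanokinError):
    """Too few observations for the requested estimate."""


class AmbiguousBaselineError(NanokinError):
    """The all-points histogram has no dominant mode; the static blockage
    level must be chosen manually."""


class DetectionError(NanokinError):
    """Event detection cannot proceed (e.g. threshold inside the noise band)."""


class SublevelCollapseWarning(UserWarning):
    """Requested sub-level count not supported by the data; levels merged."""


class SingleCycleWarning(UserWarning):
    """An irreversible run's reload rule never fires; one cycle simulated."""


class TrivialModelWarning(UserWarning):
    """Classifier trained on a single class; it will always predict it."""


class NegativeSlopeWarning(UserWarning):
    """Association-rate titration produced a non-positive slope."""
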