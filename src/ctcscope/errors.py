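"""Exception types shared across the pipeline.

Each stage raises a specific subclass so the CLI can map failures to
distinct exit codes (config vs. data vs. leakage).
"""


class CtcScopeError(Exception):
    """Base class for all package errors."""


class ConfigError(CtcScopeError):
    """Invalid or incomplete run configuration."""


class ParameterError(CtcScopeError, ValueError):
    """An operation parameter is out of its documented range."""


class PlacementError(CtcScopeError):
    """The frame cannot hold the requested cell population at the
    configured spacing/density."""


class FormatError(CtcScopeError):
    """On-disk artifact malformed (e.g. channel shape mismatch)."""


class DegenerateHistogramError(CtcScopeError):
    """Otsu thresholding asked to split a constant intensity sample."""


class DegeneratePatchError(CtcScopeError):
    """Crop normalization applied to a patch with no residual variance."""


class ClassCoverageError(CtcScopeError):
    """A labeled-data operation received zero examples of some class."""


class LeakageError(CtcScopeError):
    """Train/validation/test sets share an origin crop — a hard failure."""


class BackboneUnavailableError(CtcScopeError):
    """Requested pretrained backbone cannot be constructed offline."""


class UndefinedAUCError(CtcScopeError):
    """ROC/AUC requested for a single-class ground truth."""


class DegenerateMetricWarning(UserWarning):
    """A metric hit a degenerate case (e.g. zero precision+recall) and
    returned its documented fallback value."""
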