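"""Exception hierarchy for dsfusion."""


class DSFusionError(Exception):
    """Base class for all dsfusion errors."""


class ValidationError(DSFusionError):
    """Input violates a structural precondition (bad subset, bad range, ...)."""


class DegenerateInputError(DSFusionError):
    """Input is structurally valid but carries no usable information."""


class TotalConflictError(DSFusionError):
    """Dempster's rule is undefined: the evidences are in total conflict (k = 1)."""


class UnsupportedInputError(DSFusionError):
    """The operation is not defined for this kind of mass function."""


class UndefinedEntropyError(DSFusionError):
    """Entropy is undefined for this mass function (zero belief on a focal set)."""


class ConfigurationError(DSFusionError):
    """Unknown scheme/metric/mode name or inconsistent run configuration."""
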