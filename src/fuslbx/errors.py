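"""Exception hierarchy shared across the package."""


class FusLbxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FusLbxError, ValueError):
    """A simulator or analyzer configuration violates an invariant.

    The message names the offending field.
    """


class InputError(FusLbxError, ValueError):
    """Caller-supplied data is malformed (non-finite samples, empty bands,
    out-of-bounds windows, ...)."""


class AnalysisError(FusLbxError, RuntimeError):
    """An analysis stage cannot proceed (no baseline pulses, empty ROI,
    no opening detected, ...)."""


class DegenerateVarianceError(AnalysisError):
    """Paired differences have zero variance; the t statistic is undefined."""


class QuantitationRangeError(FusLbxError, ValueError):
    """An optical density lies outside the open response interval of the
    4PL curve (below/above the quantitation limit)."""


class FittingError(FusLbxError, RuntimeError):
    """A nonlinear fit failed on degenerate input."""


class ParameterError(FusLbxError, ValueError):
    """Pharmacokinetic parameters are outside their physical domain."""
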