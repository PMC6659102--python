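"""Exception hierarchy shared across the analysis stages."""


class HippoEphysError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HippoEphysError, ValueError):
    """A file or sidecar metadata record could not be interpreted."""


class DataError(HippoEphysError, ValueError):
    """Input data violate a structural requirement (non-finite, out of bounds...)."""


class ParameterError(HippoEphysError, ValueError):
    """A parameter is outside its valid domain (e.g. cutoff above Nyquist)."""


class BoundsError(HippoEphysError, ValueError):
    """A requested time window falls outside the trace."""


class DegenerateInputError(HippoEphysError, ValueError):
    """Input is degenerate for the requested statistic (flat trace, zero sd)."""


class ShapeError(HippoEphysError, ValueError):
    """A waveform lacks the morphological feature the estimator needs."""


class FitError(HippoEphysError, RuntimeError):
    """A model fit failed or produced a non-physical result."""


class EmptyResultError(HippoEphysError, RuntimeError):
    """An operation produced no usable output (e.g. no spikes survived filters)."""
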