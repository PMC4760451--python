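"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`SlicephysError`
so callers (and the CLI) can catch one base class.
"""


class SlicephysError(Exception):
    """Base class for all slicephys errors."""


class ValidationError(SlicephysError):
    """A domain object violates one of its invariants."""


class FormatError(SlicephysError):
    """Unknown or malformed file format."""


class MetadataError(SlicephysError):
    """Required recording metadata (dt, mode, ...) is missing or invalid."""


class SamplingError(SlicephysError):
    """Sampling interval incompatible with the requested analysis."""


class ParameterError(SlicephysError):
    """An analysis/generator parameter is out of its admissible range."""


class FitError(SlicephysError):
    """A model fit failed to converge or was ill-posed."""


class FeatureError(SlicephysError):
    """A waveform feature could not be extracted (criterion never met)."""


class BaselineError(SlicephysError):
    """Baseline/noise estimation degenerate (e.g. constant trace)."""


class MissingDependencyError(SlicephysError):
    """An optional reader backend is not installed."""
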