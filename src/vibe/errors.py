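"""Exception hierarchy for the extraction pipeline.

Errors are split into two families so the command line interface can map
them onto exit codes: :class:`InputError` covers malformed files and
invalid arguments (exit code 2), :class:`StageError` covers failures of a
pipeline stage on well-formed input (exit code 3).
"""


class VibeError(Exception):
    """Base class for all package errors."""


class InputError(VibeError):
    """Malformed input file or invalid argument."""


class FormatError(InputError):
    """A file could not be decoded as the expected format."""


class GeometryError(InputError):
    """Two images that must share a grid do not."""


class StageError(VibeError):
    """A pipeline stage failed on valid input."""

    #: name of the pipeline stage, filled in by the orchestrator
    stage: str | None = None


class DegenerateHistogramError(StageError):
    """Histogram matching got a constant source or reference image."""


class EmptyAtlasSliceError(StageError):
    """The central slice of the resampled atlas contains no brain."""


class LocalizationError(StageError):
    """Brain localization produced a center outside the field of view."""


class OverlapError(StageError):
    """Fixed and moving images do not overlap under the current transform."""


class OptimizerDivergenceError(StageError):
    """The registration metric became non-finite during optimization."""


class ExtractionError(StageError):
    """Binarization of the registered atlas produced an empty mask."""


class UndefinedMetricError(VibeError):
    """An overlap metric is undefined for the given masks (e.g. both empty)."""


class DegenerateClusterError(StageError):
    """Fewer distinct intensities than requested clusters."""


class PhantomSpecError(InputError):
    """A phantom specification is geometrically impossible."""
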