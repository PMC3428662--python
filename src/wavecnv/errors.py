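"""Exception hierarchy.

Every error raised by the library derives from :class:`WavecnvError`, so
callers can catch one type at pipeline level and map it to an exit status.
"""


class WavecnvError(Exception):
    """Base class for all wavecnv errors."""


class InvalidSequenceError(WavecnvError):
    """Probe sequence is not a 25-mer over {A, C, G, T}."""


class InvalidModelError(WavecnvError):
    """Energy model is incomplete or inconsistent with the probes."""


class InvalidInputError(WavecnvError):
    """A scalar or array argument violates its domain (non-finite, negative...)."""


class DegenerateInputError(WavecnvError):
    """Input carries no usable signal (e.g. constant intensities)."""


class ConvergenceError(WavecnvError):
    """Iterative fit failed to decrease its objective.

    Carries the best model seen so far in ``best_model``.
    """

    def __init__(self, message, best_model=None):
        super().__init__(message)
        self.best_model = best_model


class SingularDesignError(WavecnvError):
    """Probeset design matrix is rank deficient."""


class UnderdeterminedError(WavecnvError):
    """Fewer probes than regression coefficients."""


class SampleQualityError(WavecnvError):
    """Too many probesets failed for one sample."""


class DegenerateSampleError(WavecnvError):
    """A sample has a zero or non-finite median concentration."""


class DegenerateLocusError(WavecnvError):
    """A locus has zero median across the reference pool."""


class InsufficientReferenceError(WavecnvError):
    """Reference pool smaller than the hard minimum of 3 samples."""


class LocusAlignmentError(WavecnvError):
    """Track and adjustment factors disagree on loci."""


class DegenerateTrackError(WavecnvError):
    """Track median is zero; cannot rescale."""


class InvalidDistanceError(WavecnvError):
    """Inter-locus distance must be a positive integer."""


class InvalidObservationError(WavecnvError):
    """Non-finite raw copy-number observation."""


class InvalidRegionError(WavecnvError):
    """Malformed genomic region (start >= end, NaN coordinate...)."""


class FormatError(WavecnvError):
    """A TSV/JSON input violates its declared format."""


class DuplicateIdError(FormatError):
    """Duplicate probe identifier in an annotation file."""


class ConfigError(WavecnvError):
    """Invalid simulation or pipeline configuration."""
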