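"""Between-array normalization and per-locus amplification calibration.

Two median-based rescalings turn total allelic concentrations N_mk into the
raw copy-number track used for segmentation:

* normalization: N'_mk = N_mk * alpha_m with alpha_m = 2 / median_k(N_mk),
  removing array-wide scale differences (library preparation, scanner gain);
  after it every sample's median equals the diploid 2.

* calibration: N^_mk = N'_mk * gamma_k with gamma_k = 2 / median_m(N'_mk)
  taken over a reference pool of M arrays.  Per-locus amplification
  efficiencies (the "genomic waves") are stable from one array to the next,
  so dividing by the pool's per-locus median cancels them; the median keeps
  the factor robust to CNV carriers inside the pool as long as they are a
  minority at any one locus.

The diploid target constant 2 is baked into both factors; reference pools
containing sex chromosomes of mixed-sex samples are the caller's
responsibility (drop chrX/chrY from the pool, or calibrate them separately).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateLocusError,
    DegenerateSampleError,
    InsufficientReferenceError,
    LocusAlignmentError,
)

#: (probeset_id, chrom, position) triple identifying one locus
Locus = tuple[str, str, int]


@dataclass
class ConcentrationMatrix:
    """K loci x M samples grid of total concentrations, genome-ordered."""

    loci: list[Locus]
    samples: list[str]
    values: np.ndarray  # (K, M)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        K, M = len(self.loci), len(self.samples)
        if self.values.shape != (K, M):
            raise ValueError(
                f"values shape {self.values.shape} != ({K} loci, {M} samples)"
            )
        if K < 1 or M < 1:
            raise ValueError("need at least one locus and one sample")
        keys = [(chrom, pos) for _, chrom, pos in self.loci]
        if keys != sorted(keys):
            raise ValueError("loci must be sorted by (chrom, position)")

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample_id)]

    def subset_samples(self, sample_ids) -> "ConcentrationMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return ConcentrationMatrix(
            loci=list(self.loci),
            samples=list(sample_ids),
            values=self.values[:, idx].copy(),
        )


@dataclass
class NormalizationFactors:
    """Per-sample factors alpha_m = 2 / median_k(N_mk)."""

    samples: list[str]
    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)


@dataclass
class AdjustmentFactors:
    """Per-locus factors gamma_k = 2 / median_m(N'_mk) from a reference pool."""

    loci: list[Locus]
    gamma: np.ndarray
    reference_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)


@dataclass
class RawCNTrack:
    """One sample's per-locus raw copy numbers, genome-ordered."""

    sample_id: str
    loci: list[Locus]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.loci),):
            raise ValueError("one value per locus required")


def normalize_arrays(
    matrix: ConcentrationMatrix,
) -> tuple[ConcentrationMatrix, NormalizationFactors]:
    """Rescale each sample so its median concentration is the diploid 2."""
    medians = np.median(matrix.values, axis=0)
    bad = [
        s
        for s, med in zip(matrix.samples, medians)
        if not np.isfinite(med) or med <= 0
    ]
    if bad:
        raise DegenerateSampleError(
            f"zero or non-finite median concentration for sample(s) {bad}"
        )
    alpha = 2.0 / medians
    out = ConcentrationMatrix(
        loci=list(matrix.loci),
        samples=list(matrix.samples),
        values=matrix.values * alpha[np.newaxis, :],
    )
    return out, NormalizationFactors(samples=list(matrix.samples), alpha=alpha)


def fit_adjustment_factors(
    reference: ConcentrationMatrix, min_ref: int = 10
) -> AdjustmentFactors:
    """Per-locus calibration factors from a pool of normalized reference arrays."""
    M = len(reference.samples)
    if M < 3:
        raise InsufficientReferenceError(
            f"reference pool has {M} samples; at least 3 required"
        )
    if M < min_ref:
        warnings.warn(
            f"reference pool has {M} samples; >= {min_ref} recommended",
            stacklevel=2,
        )
    medians = np.median(reference.values, axis=1)
    bad = [
        reference.loci[k][0]
        for k in np.flatnonzero(~(np.isfinite(medians) & (medians > 0)))
    ]
    if bad:
        raise DegenerateLocusError(
            f"{len(bad)} locus/loci with zero reference median, "
            f"first: {bad[:5]}"
        )
    return AdjustmentFactors(
        loci=list(reference.loci),
        gamma=2.0 / medians,
        reference_samples=list(reference.samples),
    )


def calibrate(track: RawCNTrack, factors: AdjustmentFactors) -> RawCNTrack:
    """Apply per-locus factors: N^_mk = N'_mk * gamma_k (order preserved)."""
    if track.loci != factors.loci:
        raise LocusAlignmentError(
            "track and adjustment factors cover different loci"
        )
    return RawCNTrack(
        sample_id=track.sample_id,
        loci=list(track.loci),
        values=track.values * factors.gamma,
    )


def tracks_from_matrix(matrix: ConcentrationMatrix) -> list[RawCNTrack]:
    """Split a concentration matrix into one track per sample."""
    return [
        RawCNTrack(sample_id=s, loci=list(matrix.loci), values=matrix.values[:, j])
        for j, s in enumerate(matrix.samples)
    ]
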