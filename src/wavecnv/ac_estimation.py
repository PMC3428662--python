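"""Per-probeset OLS estimation of allelic concentrations.

Rearranging the additive hybridization model, each probe row of a probeset
gives one linear equation in the unknown allelic concentrations: the design
row is [1/(1+exp(E_A)), 1/(1+exp(E_B)), 1] for an SNP probeset (the last
column being a single shared background intercept per probeset and sample)
and [1/(1+exp(E)), 1] for a nonpolymorphic one.  With several probes per
probeset the ordinary least squares solution is an unbiased estimate of
(N_A, N_B, I_bg).  Cross-hybridization is corrected by construction: an
A-probe's E_A is its perfect-duplex energy while its E_B is the mismatched
duplex energy (and conversely for B-probes), so off-target binding is part
of the design rather than a bias.

Negative OLS coefficients for concentrations are truncated to zero and
flagged (``clipped``); the unconstrained fit is kept for residuals so the
flag carries the information downstream.

A single-probe nonpolymorphic probeset cannot support both a concentration
and a background parameter; its background is fixed to a per-array constant
(see :func:`array_background`) and N solved directly from the Langmuir term.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidInputError,
    InvalidModelError,
    SampleQualityError,
    SingularDesignError,
    UnderdeterminedError,
)
from .probe_model import EnergyModel, ProbeRecord, langmuir_fraction, probe_energies

logger = logging.getLogger(__name__)


@dataclass
class Probeset:
    """All probes interrogating one SNP or one nonpolymorphic (NP) locus."""

    probeset_id: str
    locus_type: str  # "SNP" or "NP"
    probes: list[ProbeRecord]
    chrom: str
    position: int

    def __post_init__(self):
        if self.locus_type not in ("SNP", "NP"):
            raise InvalidInputError(
                f"{self.probeset_id}: locus_type must be SNP or NP"
            )
        if any(p.probeset_id != self.probeset_id for p in self.probes):
            raise InvalidInputError(
                f"{self.probeset_id}: probes carry a foreign probeset_id"
            )
        if self.locus_type == "SNP":
            alleles = {p.target_allele for p in self.probes}
            if len(self.probes) < 2 or not {"A", "B"} <= alleles:
                raise InvalidInputError(
                    f"{self.probeset_id}: SNP probesets need >= 2 probes "
                    "covering both alleles"
                )
        elif not self.probes:
            raise InvalidInputError(f"{self.probeset_id}: empty NP probeset")


@dataclass
class AlleleConcentrationEstimate:
    """OLS estimate for one probeset on one array.

    ``N_total = N_A + N_B`` always; for NP loci the whole concentration is
    reported in both N_A and N_total with N_B = 0.
    """

    probeset_id: str
    sample_id: str
    N_A: float
    N_B: float
    background: float
    residual_sd: float
    clipped: bool
    chrom: str = ""
    position: int = 0

    @property
    def N_total(self) -> float:
        return self.N_A + self.N_B


def design_matrix(probeset: Probeset, model: EnergyModel) -> np.ndarray:
    """Langmuir design matrix of a probeset under an energy model.

    SNP rows: [f(E_A), f(E_B), 1] with f the Langmuir fraction; an A-probe's
    E_A is the match energy and E_B the central-mismatch energy, a B-probe's
    the converse.  NP rows: [f(E), 1].
    """
    try:
        e_match, e_mismatch = probe_energies(
            model, [p.sequence for p in probeset.probes]
        )
    except (KeyError, IndexError) as exc:  # defensive: malformed table
        raise InvalidModelError(f"model incomplete for {probeset.probeset_id}") from exc
    ones = np.ones(len(probeset.probes))
    if probeset.locus_type == "NP":
        return np.column_stack([langmuir_fraction(e_match), ones])
    is_a = np.array([p.target_allele == "A" for p in probeset.probes])
    e_a = np.where(is_a, e_match, e_mismatch)
    e_b = np.where(is_a, e_mismatch, e_match)
    return np.column_stack(
        [langmuir_fraction(e_a), langmuir_fraction(e_b), ones]
    )


def estimate_probeset(
    probeset: Probeset,
    intensities,
    model: EnergyModel,
    sample_id: str = "",
    fixed_background: float | None = None,
) -> AlleleConcentrationEstimate:
    """Solve one probeset's concentrations by ordinary least squares.

    ``intensities`` holds one value per probe in probe order.  For a
    single-probe NP probeset ``fixed_background`` must be supplied (one
    observation cannot identify two parameters); N is then solved from the
    Langmuir term alone.
    """
    y = np.asarray(intensities, dtype=float)
    if y.shape != (len(probeset.probes),):
        raise InvalidInputError(
            f"{probeset.probeset_id}: expected {len(probeset.probes)} "
            f"intensities, got {y.shape}"
        )
    if not np.all(np.isfinite(y)):
        raise InvalidInputError(f"{probeset.probeset_id}: non-finite intensity")

    X = design_matrix(probeset, model)
    n, p = X.shape

    if probeset.locus_type == "NP" and n == 1:
        if fixed_background is None:
            raise UnderdeterminedError(
                f"{probeset.probeset_id}: single-probe NP probeset needs a "
                "fixed per-array background"
            )
        frac = X[0, 0]
        raw = (y[0] - fixed_background) / frac
        clipped = raw < 0
        return AlleleConcentrationEstimate(
            probeset_id=probeset.probeset_id,
            sample_id=sample_id,
            N_A=max(raw, 0.0),
            N_B=0.0,
            background=fixed_background,
            residual_sd=0.0,
            clipped=bool(clipped),
            chrom=probeset.chrom,
            position=probeset.position,
        )

    if n < p:
        raise UnderdeterminedError(
            f"{probeset.probeset_id}: {n} probes cannot identify {p} coefficients"
        )
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(
            f"{probeset.probeset_id}: rank-deficient design matrix"
        )

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    residual_sd = math.sqrt(rss / (n - p)) if n > p else 0.0

    if probeset.locus_type == "SNP":
        n_a, n_b, bg = coef
    else:
        n_a, bg = coef
        n_b = 0.0
    clipped = bool(n_a < 0 or n_b < 0)
    return AlleleConcentrationEstimate(
        probeset_id=probeset.probeset_id,
        sample_id=sample_id,
        N_A=max(float(n_a), 0.0),
        N_B=max(float(n_b), 0.0),
        background=float(bg),
        residual_sd=residual_sd,
        clipped=clipped,
        chrom=probeset.chrom,
        position=probeset.position,
    )


def array_background(probesets, intensity_map) -> float:
    """Fallback per-array background: median of the lowest intensity decile.

    Used for single-probe NP probesets only when the array carries no SNP
    probesets; biased upward by whatever specific signal the lowest-affinity
    probes retain, so the SNP-derived estimate of :func:`estimate_sample` is
    preferred whenever available.
    """
    vals = np.asarray(
        [
            intensity_map[p.probe_id]
            for ps in probesets
            for p in ps.probes
            if p.probe_id in intensity_map
        ],
        dtype=float,
    )
    if vals.size == 0:
        raise InvalidInputError("no intensities to estimate background from")
    vals.sort()
    decile = vals[: max(1, math.ceil(0.1 * vals.size))]
    return float(np.median(decile))


def estimate_sample(
    probesets,
    intensity_map,
    model: EnergyModel,
    sample_id: str = "",
    max_failure_fraction: float = 0.5,
) -> list[AlleleConcentrationEstimate]:
    """Estimate every probeset for one sample, genome-ordered.

    ``intensity_map`` maps probe_id to intensity (a dict or pandas Series).
    SNP (and multi-probe NP) probesets are solved first; the median of their
    fitted backgrounds becomes the fixed per-array background for
    single-probe NP probesets (falling back to the lowest-decile rule on
    arrays without SNP probesets).  Failed probesets (singular or
    underdetermined designs) are skipped with a warning; more than
    ``max_failure_fraction`` failures aborts the sample.
    """
    probesets = sorted(
        probesets, key=lambda ps: (ps.chrom, ps.position, ps.probeset_id)
    )

    def probe_values(ps):
        try:
            return [float(intensity_map[p.probe_id]) for p in ps.probes]
        except KeyError as exc:
            raise InvalidInputError(
                f"sample {sample_id}: missing intensity for probe {exc}"
            ) from exc

    estimates: dict[int, AlleleConcentrationEstimate] = {}
    failures = []
    deferred = []  # single-probe NP probesets wait for the background constant
    for i, ps in enumerate(probesets):
        if ps.locus_type == "NP" and len(ps.probes) == 1:
            deferred.append(i)
            continue
        try:
            estimates[i] = estimate_probeset(
                ps, probe_values(ps), model, sample_id=sample_id
            )
        except (SingularDesignError, UnderdeterminedError) as exc:
            failures.append((ps.probeset_id, str(exc)))

    if deferred:
        if estimates:
            bg0 = float(np.median([e.background for e in estimates.values()]))
        else:
            bg0 = array_background(probesets, intensity_map)
        for i in deferred:
            ps = probesets[i]
            try:
                estimates[i] = estimate_probeset(
                    ps, probe_values(ps), model, sample_id=sample_id,
                    fixed_background=bg0,
                )
            except (SingularDesignError, UnderdeterminedError) as exc:
                failures.append((ps.probeset_id, str(exc)))
    if failures:
        logger.warning(
            "sample %s: skipped %d probeset(s), first: %s",
            sample_id,
            len(failures),
            failures[0][1],
        )
    if probesets and len(failures) > max_failure_fraction * len(probesets):
        raise SampleQualityError(
            f"sample {sample_id}: {len(failures)}/{len(probesets)} probesets failed"
        )
    return [estimates[i] for i in sorted(estimates)]
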