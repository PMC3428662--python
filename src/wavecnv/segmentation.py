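"""Distance-aware five-state HMM segmentation of the raw copy-number track.

The hidden state of each locus is its true integer copy number, one of
{0, 1, 2, 3, >=4}; the observation is the calibrated raw copy number.
Emissions are Gaussian with the state's copy number as mean and a shared
standard deviation.  Transitions depend on the genomic gap d between
neighboring loci through

    A(d) = (1 - f) * I + f * B,     f = 1 - exp(-d / D),

where B is the base transition matrix (leaving the normal diploid state is
rare, returning to it is comparatively likely) and D a length scale
(default 100 kb).  Adjacent loci (d -> 0) are then effectively locked to the
same state while distant loci forget each other (A -> B), which is what
physical linkage of copy-number segments demands.

Decoding is exact Viterbi in log space; ties break toward the lower copy
state, so a deletion wins an exact tie against an amplification.  Parameter
refinement uses Viterbi training (hard EM): decode, re-estimate the shared
emission sd and the base transition counts from the decoded path, repeat
until the path stops changing.  The state means are never re-estimated —
they anchor the states to integer copy numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    InvalidDistanceError,
    InvalidInputError,
    InvalidObservationError,
)
from .normalization import RawCNTrack

N_STATES = 5
STATE_COPY_NUMBERS = (0, 1, 2, 3, 4)  # state 4 means CN >= 4

_LOG_2PI = float(np.log(2.0 * np.pi))


def _default_base_transition() -> np.ndarray:
    out = np.full((N_STATES, N_STATES), 1e-4)
    normal = 2
    out[normal, :] = 1e-4
    out[:, normal] = 0.05
    for s in range(N_STATES):
        out[s, s] = 0.0
        out[s, s] = 1.0 - out[s].sum()
    return out


def _default_initial() -> np.ndarray:
    init = np.full(N_STATES, 1e-3)
    init[2] = 1.0 - init.sum() + init[2]
    return init


@dataclass
class HMMParameters:
    """Emission, transition and distance parameters of the copy-number HMM."""

    emission_means: np.ndarray = field(
        default_factory=lambda: np.array(STATE_COPY_NUMBERS, dtype=float)
    )
    emission_sd: float = 0.4
    initial_dist: np.ndarray = field(default_factory=_default_initial)
    base_transition: np.ndarray = field(default_factory=_default_base_transition)
    distance_scale: int = 100_000  # D, bp

    def __post_init__(self):
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        self.base_transition = np.asarray(self.base_transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.emission_means.shape != (N_STATES,):
            raise InvalidInputError("emission_means must have 5 entries")
        if self.emission_sd <= 0:
            raise InvalidInputError("emission_sd must be positive")
        if self.initial_dist.shape != (N_STATES,) or np.any(self.initial_dist < 0):
            raise InvalidInputError("initial_dist must be 5 nonnegative reals")
        if abs(self.initial_dist.sum() - 1.0) > 1e-12:
            raise InvalidInputError("initial_dist must sum to 1")
        if self.base_transition.shape != (N_STATES, N_STATES):
            raise InvalidInputError("base_transition must be 5x5")
        if np.any(self.base_transition < 0) or np.any(
            np.abs(self.base_transition.sum(axis=1) - 1.0) > 1e-12
        ):
            raise InvalidInputError("base_transition rows must sum to 1")
        if self.distance_scale <= 0:
            raise InvalidInputError("distance_scale must be positive")

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "emission_means": self.emission_means.tolist(),
            "emission_sd": float(self.emission_sd),
            "initial_dist": self.initial_dist.tolist(),
            "base_transition": self.base_transition.tolist(),
            "distance_scale": int(self.distance_scale),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParameters":
        return cls(
            emission_means=np.asarray(d["emission_means"], dtype=float),
            emission_sd=float(d["emission_sd"]),
            initial_dist=np.asarray(d["initial_dist"], dtype=float),
            base_transition=np.asarray(d["base_transition"], dtype=float),
            distance_scale=int(d["distance_scale"]),
        )

    @classmethod
    def from_json(cls, path) -> "HMMParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SegmentationResult:
    """Decoded state path for one sample (possibly one chromosome of it)."""

    sample_id: str
    path: np.ndarray  # int state indices, one per locus
    log_probability: float
    iterations: int = 0
    converged: bool = True

    def __post_init__(self):
        self.path = np.asarray(self.path, dtype=int)


@dataclass
class CNVCall:
    """A maximal constant-copy-state aberrant interval (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: int
    n_probes: int
    mean_raw_cn: float

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidInputError("call must satisfy start < end")
        if self.copy_state == 2:
            raise InvalidInputError("calls are aberrant states only (CN != 2)")


def transition_matrix(d: int, params: HMMParameters) -> np.ndarray:
    """Distance-dependent transition matrix A(d) = (1-f) I + f B."""
    if d <= 0:
        raise InvalidDistanceError(f"inter-locus distance must be >= 1, got {d}")
    f = 1.0 - np.exp(-float(d) / params.distance_scale)
    return (1.0 - f) * np.eye(N_STATES) + f * params.base_transition


def _check_track(track: RawCNTrack) -> None:
    positions = [pos for _, _, pos in track.loci]
    chroms = {chrom for _, chrom, _ in track.loci}
    if len(chroms) > 1:
        raise InvalidInputError(
            f"viterbi expects a single chromosome, got {sorted(chroms)}"
        )
    if positions != sorted(positions):
        raise InvalidInputError("loci must be sorted by position")
    bad = np.flatnonzero(~np.isfinite(track.values))
    if bad.size:
        raise InvalidObservationError(
            f"non-finite raw CN at locus {track.loci[bad[0]]}"
        )


def _log_emissions(values: np.ndarray, params: HMMParameters) -> np.ndarray:
    """(n, 5) matrix of log N(value; mean_s, sd^2)."""
    sd = params.emission_sd
    z = (values[:, None] - params.emission_means[None, :]) / sd
    return -0.5 * z**2 - np.log(sd) - 0.5 * _LOG_2PI


def viterbi(track: RawCNTrack, params: HMMParameters) -> SegmentationResult:
    """Exact maximum-probability state path for one chromosome.

    Log-space dynamic programming; exact ties break toward the lower copy
    state (argmax returns the first maximum).
    """
    if len(track.loci) == 0:
        return SegmentationResult(
            sample_id=track.sample_id,
            path=np.empty(0, dtype=int),
            log_probability=0.0,
        )
    _check_track(track)
    n = len(track.loci)
    logem = _log_emissions(track.values, params)
    positions = np.array([pos for _, _, pos in track.loci])

    with np.errstate(divide="ignore"):
        delta = np.log(params.initial_dist) + logem[0]
        backptr = np.zeros((n, N_STATES), dtype=int)
        for t in range(1, n):
            d = int(positions[t] - positions[t - 1])
            logA = np.log(transition_matrix(max(d, 1), params))
            cand = delta[:, None] + logA  # cand[i, j]
            backptr[t] = np.argmax(cand, axis=0)
            delta = cand[backptr[t], np.arange(N_STATES)] + logem[t]

    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    logp = float(delta[path[-1]])
    for t in range(n - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return SegmentationResult(
        sample_id=track.sample_id, path=path, log_probability=logp
    )


def viterbi_train(
    track: RawCNTrack,
    params: HMMParameters,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> tuple[HMMParameters, SegmentationResult]:
    """Hard-EM refinement: alternate decoding and re-estimation.

    The shared emission sd is re-estimated as the pooled standard deviation
    of (observation - decoded state mean), floored at 0.05; the base
    transition matrix from Laplace-smoothed (+1) transition counts along the
    decoded path.  Stops when the decoded path repeats or after
    ``max_iter`` iterations.  State means and the distance scale are fixed.
    """
    result = viterbi(track, params)
    if max_iter <= 0 or len(track.loci) == 0:
        return params, result
    prev_path = result.path
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        params = _reestimate(track, prev_path, params)
        result = viterbi(track, params)
        if np.array_equal(result.path, prev_path):
            converged = True
            break
        prev_path = result.path
    result = replace(
        result, iterations=iterations, converged=converged
    )
    return params, result


def _reestimate(
    track: RawCNTrack, path: np.ndarray, params: HMMParameters
) -> HMMParameters:
    resid = track.values - params.emission_means[path]
    sd = float(np.sqrt(np.mean(resid**2))) if resid.size else params.emission_sd
    # cap at the nearest-state deviation: an oversmoothed path must not
    # inflate the emission width it is then re-decoded with
    nearest = np.min(
        np.abs(track.values[:, None] - params.emission_means[None, :]), axis=1
    )
    sd = min(sd, float(np.sqrt(np.mean(nearest**2))) if nearest.size else sd)
    sd = max(sd, 0.05)
    counts = np.ones((N_STATES, N_STATES))  # Laplace +1
    for a, b in zip(path[:-1], path[1:]):
        counts[a, b] += 1
    base = counts / counts.sum(axis=1, keepdims=True)
    return HMMParameters(
        emission_means=params.emission_means.copy(),
        emission_sd=sd,
        initial_dist=params.initial_dist.copy(),
        base_transition=base,
        distance_scale=params.distance_scale,
    )


def extract_calls(
    result: SegmentationResult,
    loci,
    values=None,
    min_probes: int = 5,
) -> list[CNVCall]:
    """Turn maximal non-diploid runs of the decoded path into CNV calls.

    Coordinates are 0-based half-open: a run spanning 1-based locus
    positions p_first..p_last becomes [p_first - 1, p_last).  Runs shorter
    than ``min_probes`` loci are dropped (sub-5-probe regions are below the
    array's design resolution).
    """
    loci = list(loci)
    path = result.path
    if len(path) != len(loci):
        raise InvalidInputError("path and loci lengths differ")
    if values is not None:
        values = np.asarray(values, dtype=float)
    calls: list[CNVCall] = []
    i = 0
    n = len(path)
    while i < n:
        state = path[i]
        chrom = loci[i][1]
        j = i
        while j + 1 < n and path[j + 1] == state and loci[j + 1][1] == chrom:
            j += 1
        if state != 2 and (j - i + 1) >= min_probes:
            mean_cn = float(values[i : j + 1].mean()) if values is not None else float("nan")
            calls.append(
                CNVCall(
                    sample_id=result.sample_id,
                    chrom=chrom,
                    start=loci[i][2] - 1,
                    end=loci[j][2],
                    copy_state=int(state),
                    n_probes=j - i + 1,
                    mean_raw_cn=mean_cn,
                )
            )
        i = j + 1
    return calls


def segment_track(
    track: RawCNTrack,
    params: HMMParameters | None = None,
    min_probes: int = 5,
    train: bool = True,
    max_iter: int = 20,
) -> tuple[list[CNVCall], list[SegmentationResult]]:
    """Segment a whole-genome track chromosome by chromosome.

    Each chromosome is decoded independently (with the initial distribution
    applied at its first locus); Viterbi training is per chromosome.
    Returns the concatenated CNV calls and the per-chromosome results.
    """
    if params is None:
        params = HMMParameters()
    calls: list[CNVCall] = []
    results: list[SegmentationResult] = []
    for chrom_track in split_by_chromosome(track):
        if train:
            _, result = viterbi_train(chrom_track, params, max_iter=max_iter)
        else:
            result = viterbi(chrom_track, params)
        results.append(result)
        calls.extend(
            extract_calls(
                result, chrom_track.loci, chrom_track.values, min_probes=min_probes
            )
        )
    return calls, results


def split_by_chromosome(track: RawCNTrack) -> list[RawCNTrack]:
    """Split a genome-ordered track into per-chromosome tracks."""
    out = []
    i = 0
    n = len(track.loci)
    while i < n:
        chrom = track.loci[i][1]
        j = i
        while j + 1 < n and track.loci[j + 1][1] == chrom:
            j += 1
        out.append(
            RawCNTrack(
                sample_id=track.sample_id,
                loci=track.loci[i : j + 1],
                values=track.values[i : j + 1],
            )
        )
        i = j + 1
    return out
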