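"""Physicochemical model of probe-target hybridization.

Probe intensity on an SNP array is modelled as Langmuir-like adsorption of
target DNA onto a 25-mer oligonucleotide probe.  The occupied fraction of
probe sites is ``1 / (1 + exp(E))`` where ``E`` is the duplex binding free
energy, and ``E`` itself follows a position-dependent nearest-neighbor (PDNN)
decomposition: a position-weighted sum of the stacking energies of the 24
consecutive dinucleotide steps along the probe,

    E = sum_{i=1..24} omega_i * lambda(b_i, b_{i+1}).

A probe therefore responds to BOTH alleles of a polymorphic locus: the
matched allele binds with the perfect-duplex energy, the off-target allele
binds with a weaker (higher-E) energy in which the two steps flanking the
central base (position 13 of 25) draw from a mismatch stacking table.  The
observed intensity is the additive combination

    I = N_A / (1 + exp(E_A)) + N_B / (1 + exp(E_B)) + I_bg + noise,

with N_A, N_B the allelic concentrations.  The constants (omega, lambda,
mismatch lambda) are probe-independent and can be trained from a single
array; :func:`train_energy_model` does so by alternating least squares.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    InvalidInputError,
    InvalidModelError,
    InvalidSequenceError,
)

PROBE_LENGTH = 25
N_STEPS = PROBE_LENGTH - 1
#: 0-based indices of the two dinucleotide steps spanning the central base
#: (position 13, 1-based) of a 25-mer.
CENTRAL_STEPS = (11, 12)

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
#: the 16 ordered dinucleotides, "AA", "AC", ..., "TT"
DINUCLEOTIDES = ["".join(p) for p in itertools.product(_BASES, repeat=2)]
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

_ALLELES = ("A", "B", "NP")

DEFAULT_MISMATCH_PENALTY = 2.0


@dataclass(frozen=True)
class ProbeRecord:
    """One 25-mer probe anchored to a genomic locus."""

    probe_id: str
    probeset_id: str
    target_allele: str  # "A", "B" or "NP"
    sequence: str
    chrom: str
    position: int  # 1-based
    fragment_id: str

    def __post_init__(self):
        validate_sequence(self.sequence)
        if self.target_allele not in _ALLELES:
            raise InvalidInputError(
                f"probe {self.probe_id}: target_allele must be one of "
                f"{_ALLELES}, got {self.target_allele!r}"
            )
        if self.position < 1:
            raise InvalidInputError(
                f"probe {self.probe_id}: position must be >= 1 (1-based)"
            )


@dataclass(frozen=True)
class IntensityObservation:
    """Fluorescence intensity of one probe on one array."""

    probe_id: str
    sample_id: str
    intensity: float

    def __post_init__(self):
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise InvalidInputError(
                f"intensity for probe {self.probe_id} must be finite and >= 0"
            )


def validate_sequence(sequence: str) -> None:
    """Reject anything that is not a 25-mer over {A, C, G, T}."""
    if len(sequence) != PROBE_LENGTH:
        raise InvalidSequenceError(
            f"probe sequences must have length {PROBE_LENGTH}, "
            f"got {len(sequence)}"
        )
    if any(b not in _BASE_CODE for b in sequence):
        bad = sorted({b for b in sequence if b not in _BASE_CODE})
        raise InvalidSequenceError(f"non-ACGT character(s) {bad} in sequence")


def encode_steps(sequence: str) -> np.ndarray:
    """Map a 25-mer to the indices of its 24 dinucleotide steps."""
    validate_sequence(sequence)
    codes = np.fromiter((_BASE_CODE[b] for b in sequence), dtype=np.intp)
    return codes[:-1] * 4 + codes[1:]


@dataclass
class EnergyModel:
    """PDNN stacking energies, position weights and mismatch table.

    ``weights`` (omega) has length 24 and is constrained to mean 1: omega and
    lambda are jointly identified only up to the scale swap
    (omega, lambda) -> (omega / c, lambda * c), which leaves every energy
    unchanged.  ``mismatch_stacking`` replaces ``stacking`` on the two steps
    flanking a mismatched central base.
    """

    stacking: dict[str, float]
    weights: np.ndarray
    mismatch_stacking: dict[str, float]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, table in (
            ("stacking", self.stacking),
            ("mismatch_stacking", self.mismatch_stacking),
        ):
            missing = [d for d in DINUCLEOTIDES if d not in table]
            if missing:
                raise InvalidModelError(f"{name} lacks entries for {missing}")
            vals = np.array([table[d] for d in DINUCLEOTIDES], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise InvalidModelError(f"{name} contains non-finite values")
        if self.weights.shape != (N_STEPS,):
            raise InvalidModelError(
                f"weights must have length {N_STEPS}, got {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise InvalidModelError("weights must be finite and nonnegative")
        if not np.isclose(self.weights.mean(), 1.0, atol=1e-8):
            raise InvalidModelError(
                f"weights must average 1 (identifiability constraint); "
                f"mean is {self.weights.mean():.6g}"
            )

    # -- vector views -------------------------------------------------

    def stacking_vector(self) -> np.ndarray:
        return np.array([self.stacking[d] for d in DINUCLEOTIDES], dtype=float)

    def mismatch_vector(self) -> np.ndarray:
        return np.array(
            [self.mismatch_stacking[d] for d in DINUCLEOTIDES], dtype=float
        )

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "stacking": {d: float(self.stacking[d]) for d in DINUCLEOTIDES},
            "weights": [float(w) for w in self.weights],
            "mismatch_stacking": {
                d: float(self.mismatch_stacking[d]) for d in DINUCLEOTIDES
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        try:
            return cls(
                stacking=dict(d["stacking"]),
                weights=np.asarray(d["weights"], dtype=float),
                mismatch_stacking=dict(d["mismatch_stacking"]),
            )
        except KeyError as exc:
            raise InvalidModelError(f"energy-model JSON lacks key {exc}") from exc

    @classmethod
    def from_json(cls, path) -> "EnergyModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls, mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY):
        """Untrained starting point: flat weights, zero stacking energies,
        mismatch table offset by a global penalty."""
        return cls(
            stacking={d: 0.0 for d in DINUCLEOTIDES},
            weights=np.ones(N_STEPS),
            mismatch_stacking={d: mismatch_penalty for d in DINUCLEOTIDES},
        )


def binding_energy(
    model: EnergyModel, sequence: str, mismatch_center: bool = False
) -> float:
    """PDNN binding free energy of a probe-target duplex.

    With ``mismatch_center`` the two steps touching the central base
    (positions 12-13 and 13-14) draw from the mismatch stacking table,
    modelling the off-target allele's duplex.
    """
    steps = encode_steps(sequence)
    lam = model.stacking_vector()[steps]
    if mismatch_center:
        mm = model.mismatch_vector()[steps]
        for i in CENTRAL_STEPS:
            lam[i] = mm[i]
    return float(np.dot(model.weights, lam))


def langmuir_fraction(E):
    """Occupied fraction of probe sites, ``1 / (1 + exp(E))``.

    Strictly decreasing in E, mapping the real line onto (0, 1); computed via
    the logistic function so large |E| neither overflows nor underflows to a
    wrong branch.  Accepts scalars or arrays.
    """
    arr = np.asarray(E, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("binding energy must be finite")
    out = expit(-arr)
    return float(out) if np.isscalar(E) or arr.ndim == 0 else out


def predict_intensity(
    N_A: float, N_B: float, E_A: float, E_B: float, background: float
) -> float:
    """Noiseless expected intensity of one probe.

    The two alleles contribute additively through their own Langmuir terms;
    background is a sequence-independent additive offset.
    """
    if N_A < 0 or N_B < 0 or background < 0:
        raise InvalidInputError("concentrations and background must be >= 0")
    return (
        N_A * langmuir_fraction(E_A)
        + N_B * langmuir_fraction(E_B)
        + background
    )


# ---------------------------------------------------------------------------
# vectorized energy evaluation (shared with estimation / simulation)
# ---------------------------------------------------------------------------


def _energies_from_vectors(
    steps: np.ndarray, weights: np.ndarray, lam: np.ndarray, mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match and mismatch energies for a (n_probes, 24) step-index matrix."""
    e_match = (lam[steps] * weights).sum(axis=1)
    e_mismatch = e_match.copy()
    for i in CENTRAL_STEPS:
        e_mismatch += weights[i] * (mm[steps[:, i]] - lam[steps[:, i]])
    return e_match, e_mismatch


def probe_energies(
    model: EnergyModel, sequences: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(match, mismatch) energy arrays for a list of 25-mers."""
    steps = np.stack([encode_steps(s) for s in sequences])
    return _energies_from_vectors(
        steps, model.weights, model.stacking_vector(), model.mismatch_vector()
    )


# ---------------------------------------------------------------------------
# single-array training
# ---------------------------------------------------------------------------


def _theta_pack(weights, lam, mm):
    return np.concatenate([weights, lam, mm])


def _theta_unpack(theta):
    return theta[:N_STEPS], theta[N_STEPS : N_STEPS + 16], theta[N_STEPS + 16 :]


def _batched_coefficients(e_a, e_b, y, size_groups):
    """Per-probe (N_A, N_B, bg) from the batched per-probeset OLS."""
    fa = expit(-e_a)
    fb = expit(-e_b)
    na = np.empty_like(y)
    nb = np.empty_like(y)
    bg = np.empty_like(y)
    for idx in size_groups:
        X = np.stack([fa[idx], fb[idx], np.ones(idx.shape)], axis=2)
        xtx = np.einsum("psi,psj->pij", X, X)
        xty = np.einsum("psi,ps->pi", X, y[idx])
        coef = np.einsum("pij,pj->pi", np.linalg.pinv(xtx), xty)
        na[idx] = coef[:, 0:1]
        nb[idx] = coef[:, 1:2]
        bg[idx] = coef[:, 2:3]
    return na, nb, bg


def _batched_fit(e_a, e_b, y, size_groups):
    """Per-probeset OLS of (N_A, N_B, bg) given energies, batched by size.

    ``size_groups`` is a list of (P, s) index matrices into the flat probe
    arrays, one per distinct probeset size s.  Returns the fitted intensity
    for every probe.  The pseudoinverse keeps the start of training (all
    energies zero, hence perfectly collinear allele columns) well defined
    via the minimum-norm solution.
    """
    fa = expit(-e_a)
    fb = expit(-e_b)
    fitted = np.empty_like(y)
    for idx in size_groups:
        X = np.stack(
            [fa[idx], fb[idx], np.ones(idx.shape)], axis=2
        )  # (P, s, 3)
        xtx = np.einsum("psi,psj->pij", X, X)
        xty = np.einsum("psi,ps->pi", X, y[idx])
        coef = np.einsum("pij,pj->pi", np.linalg.pinv(xtx), xty)
        fitted[idx] = np.einsum("psi,pi->ps", X, coef)
    return fitted


def train_energy_model(
    intensities,
    probes,
    init: EnergyModel | None = None,
    max_iter: int = 40,
    tol: float = 1e-8,
) -> EnergyModel:
    """Fit (omega, lambda, mismatch lambda) from ONE array.

    Alternates (a) per-probeset unconstrained OLS of the concentrations and
    background given the current energies with (b) a damped least-squares
    update of the energy constants, in which the concentration step is
    profiled into the residual (variable projection: every trial energy
    vector is scored at its own optimal concentrations, which is exactly the
    fixed point the plain alternation converges to, reached in far fewer
    sweeps).  omega is renormalized to mean 1 after each update, with the
    compensating rescale of both stacking tables, which leaves every energy
    unchanged.  Only SNP probesets with at least one A- and one B-probe
    enter the fit: a single-probe nonpolymorphic set cannot separate signal
    from background.

    ``intensities`` may be a mapping probe_id -> intensity, a pandas Series
    indexed by probe_id, or an iterable of :class:`IntensityObservation`
    (all for the same sample).
    """
    probes = list(probes)
    intens_map = _as_intensity_map(intensities)

    # group SNP probes by probeset, keeping only trainable probesets
    by_set: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        if p.target_allele in ("A", "B") and p.probe_id in intens_map:
            by_set.setdefault(p.probeset_id, []).append(p)
    trainable = [
        ps
        for ps in by_set.values()
        if any(p.target_allele == "A" for p in ps)
        and any(p.target_allele == "B" for p in ps)
        and len(ps) >= 4
    ]
    if len(trainable) < 500:
        warnings.warn(
            f"training on {len(trainable)} probesets; >= 500 recommended "
            "for stable energy constants",
            stacklevel=2,
        )
    if not trainable:
        raise DegenerateInputError("no trainable SNP probesets with intensities")

    flat = [p for ps in trainable for p in ps]
    y = np.array([intens_map[p.probe_id] for p in flat], dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant intensities carry no signal")
    steps = np.stack([encode_steps(p.sequence) for p in flat])
    is_a = np.array([p.target_allele == "A" for p in flat])
    by_size: dict[int, list[np.ndarray]] = {}
    start = 0
    for ps in trainable:
        by_size.setdefault(len(ps), []).append(np.arange(start, start + len(ps)))
        start += len(ps)
    size_groups = [np.stack(rows) for rows in by_size.values()]

    model = init if init is not None else EnergyModel.default()
    # omega is carried on the log scale: positivity is structural and the
    # optimizer cannot wander into sign-flipped local traps
    theta = _theta_pack(
        np.log(np.maximum(model.weights, 1e-6)),
        model.stacking_vector(),
        model.mismatch_vector(),
    )

    def energies(theta):
        u, lam, mm = _theta_unpack(theta)
        # clamp against optimizer excursions: exp overflow would poison the
        # batched solve with NaNs
        w = np.exp(np.clip(u, -30.0, 30.0))
        e_match, e_mm = _energies_from_vectors(steps, w, lam, mm)
        e_a = np.clip(np.where(is_a, e_match, e_mm), -500.0, 500.0)
        e_b = np.clip(np.where(is_a, e_mm, e_match), -500.0, 500.0)
        return e_a, e_b

    def residuals(theta):
        # (a) is embedded here: concentrations re-solved at every trial theta
        return y - _batched_fit(*energies(theta), y, size_groups)

    def objective(theta):
        return float(np.sum(residuals(theta) ** 2))

    n = y.size

    def jacobian(theta):
        # d(residual)/d(theta) holding the profiled concentrations fixed
        # (Kaufman simplification of the variable-projection derivative)
        u, lam, mm = _theta_unpack(theta)
        w = np.exp(np.clip(u, -30.0, 30.0))
        e_a, e_b = energies(theta)
        fa, fb = expit(-e_a), expit(-e_b)
        na, nb, _ = _batched_coefficients(e_a, e_b, y, size_groups)
        ga = na * fa * (1.0 - fa)  # dr/dE_A per probe
        gb = nb * fb * (1.0 - fb)

        lam_match = lam[steps]  # (n, 24) effective step energies
        lam_mm = lam_match.copy()
        for i in CENTRAL_STEPS:
            lam_mm[:, i] = mm[steps[:, i]]
        dea_dw = np.where(is_a[:, None], lam_match, lam_mm)
        deb_dw = np.where(is_a[:, None], lam_mm, lam_match)

        rows = np.arange(n)
        dmatch_dlam = np.zeros((n, 16))
        for i in range(N_STEPS):
            dmatch_dlam[rows, steps[:, i]] += w[i]
        dmm_dlam = dmatch_dlam.copy()
        dmm_dtab = np.zeros((n, 16))
        for i in CENTRAL_STEPS:
            dmm_dlam[rows, steps[:, i]] -= w[i]
            dmm_dtab[rows, steps[:, i]] += w[i]
        dea_dlam = np.where(is_a[:, None], dmatch_dlam, dmm_dlam)
        deb_dlam = np.where(is_a[:, None], dmm_dlam, dmatch_dlam)
        dea_dtab = np.where(is_a[:, None], 0.0, dmm_dtab)
        deb_dtab = np.where(is_a[:, None], dmm_dtab, 0.0)

        J = np.empty((n, theta.size))
        # chain rule for the log-scale omega: dE/du_i = omega_i * dE/domega_i
        J[:, :N_STEPS] = (ga[:, None] * dea_dw + gb[:, None] * deb_dw) * w[None, :]
        J[:, N_STEPS : N_STEPS + 16] = (
            ga[:, None] * dea_dlam + gb[:, None] * deb_dlam
        )
        J[:, N_STEPS + 16 :] = ga[:, None] * dea_dtab + gb[:, None] * deb_dtab
        return J

    def renormalized(theta):
        # mean(omega) = 1; rescale both tables to keep every energy fixed
        u, lam, mm = _theta_unpack(theta)
        scale = np.exp(u).mean()
        return _theta_pack(u - np.log(scale), lam * scale, mm * scale)

    # warm-up: fit the stacking tables at flat weights first -- the reduced
    # problem is far better conditioned and steers the full fit away from
    # poor stationary points
    u0 = _theta_unpack(theta)[0].copy()

    def tab_residuals(tabs):
        return residuals(np.concatenate([u0, tabs]))

    def tab_jacobian(tabs):
        return jacobian(np.concatenate([u0, tabs]))[:, N_STEPS:]

    warm = least_squares(
        tab_residuals, theta[N_STEPS:], jac=tab_jacobian, method="lm",
        max_nfev=200 * 32,
    )
    theta = np.concatenate([u0, warm.x])

    best_theta = theta.copy()
    best_obj = prev_obj = objective(theta)
    no_decrease = 0
    for _ in range(max_iter):
        # (b) damped least-squares sweep over the energy constants
        fit = least_squares(
            residuals, theta, jac=jacobian, method="lm",
            max_nfev=200 * theta.size,
        )
        theta = renormalized(fit.x)

        obj = objective(theta)
        if obj < best_obj:
            best_obj = obj
            best_theta = theta.copy()
        if obj >= prev_obj * (1 - 1e-15) and obj >= prev_obj:
            no_decrease += 1
            if no_decrease >= 3:
                raise ConvergenceError(
                    "objective failed to decrease for 3 consecutive iterations",
                    best_model=_theta_to_model(best_theta),
                )
        else:
            no_decrease = 0
        if prev_obj > 0 and (prev_obj - obj) / prev_obj < tol:
            prev_obj = obj
            break
        prev_obj = obj

    return _theta_to_model(best_theta)


def _theta_to_model(theta) -> EnergyModel:
    u, lam, mm = _theta_unpack(theta)
    w = np.exp(u)
    w = w / w.mean()
    return EnergyModel(
        stacking=dict(zip(DINUCLEOTIDES, lam.tolist())),
        weights=w,
        mismatch_stacking=dict(zip(DINUCLEOTIDES, mm.tolist())),
    )


def _as_intensity_map(intensities) -> dict[str, float]:
    if hasattr(intensities, "items"):
        return {str(k): float(v) for k, v in intensities.items()}
    out = {}
    for obs in intensities:
        out[obs.probe_id] = float(obs.intensity)
    return out
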