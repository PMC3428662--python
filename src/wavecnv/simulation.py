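"""Synthetic SNP-array data with full ground truth.

Emulates the data-generating assumptions behind the pipeline so every stage
is testable without array downloads:

* probeset structure of an Affymetrix-style SNP array: several A-allele and
  B-allele 25-mer probes per SNP plus single-probe nonpolymorphic loci;
* intensities from the additive Langmuir model — each allele's concentration
  times its hybridization fraction, scaled by a per-locus amplification
  factor, plus background and Gaussian noise (truncated at zero);
* "genomic waves": per-locus multiplicative amplification factors drawn as
  the exponential of a moving-average-smoothed Gaussian, IDENTICAL across
  samples — the cross-sample stability the calibration step exploits;
* Hardy-Weinberg genotypes at a configurable minor-allele frequency;
* integer copy-number ground truth with embedded CNV segments assigned to a
  random subset of carrier samples, the copy number split uniformly across
  alleles among valid integer compositions;
* optionally a second chromosome ("chrX") that is haploid in a configurable
  number of "male" samples, for sex-classification benchmarks.

Same config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .probe_model import DINUCLEOTIDES, EnergyModel, N_STEPS, probe_energies
from .segmentation import CNVCall

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic dataset.

    Defaults describe a small diploid cohort on one chromosome: 1000 loci at
    3 kb spacing, 20 samples, moderate waves (log-sd 0.3) and probe noise
    chosen so the calibrated raw-CN dispersion in diploid regions (sd around
    0.2-0.25) matches what well-behaved real arrays show.
    """

    seed: int = 0
    n_snp_loci: int = 800
    n_np_loci: int = 200
    probes_per_snp: int = 6  # half A-target, half B-target
    n_samples: int = 20
    maf: float = 0.3  # frequency of the B allele
    cnv_spec: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(1, 12, 0.3), (3, 12, 0.3), (0, 10, 0.15), (4, 10, 0.15)]
    )
    wave_sd: float = 0.3  # log-scale sd of amplification factors
    wave_correlation_span: int = 15  # moving-average span, loci
    noise_sd: float = 0.05
    background_mean: float = 0.5
    locus_spacing_bp: int = 3000
    chrom: str = "chr1"
    n_chrx_loci: int = 0  # extra SNP loci on "chrX"
    n_male_samples: int = 0  # first samples are haploid on chrX

    def __post_init__(self):
        if self.n_snp_loci < 1 or self.n_samples < 1:
            raise ConfigError("need at least one SNP locus and one sample")
        if not 0 < self.maf <= 0.5:
            raise ConfigError("maf must lie in (0, 0.5]")
        if self.probes_per_snp < 2:
            raise ConfigError("SNP probesets need at least 2 probes")
        if self.wave_sd < 0 or self.noise_sd < 0 or self.background_mean < 0:
            raise ConfigError("wave_sd, noise_sd, background_mean must be >= 0")
        if self.locus_spacing_bp < 1 or self.wave_correlation_span < 1:
            raise ConfigError("spacing and correlation span must be >= 1")
        if self.n_male_samples > self.n_samples:
            raise ConfigError("more male samples than samples")
        for state, n_loci, frac in self.cnv_spec:
            if state == 2 or not 0 <= state:
                raise ConfigError("cnv copy states must be aberrant (>= 0, != 2)")
            if n_loci < 1 or not 0 < frac <= 1:
                raise ConfigError("cnv_spec loci counts and fractions out of range")


@dataclass
class GroundTruth:
    """Everything the generator knows: the target of every recovery test."""

    loci: list[tuple[str, str, int]]  # (probeset_id, chrom, position)
    locus_type: list[str]  # "SNP" / "NP" per locus
    samples: list[str]
    cn: np.ndarray  # (K, M) int copy numbers
    dosage_a: np.ndarray  # (K, M) allele-A copies
    dosage_b: np.ndarray  # (K, M) allele-B copies
    amplification: np.ndarray  # (K,) per-locus factor, shared by samples
    energy_model: EnergyModel
    calls: list[CNVCall]


@dataclass
class SimulatedDataset:
    annotation: pd.DataFrame
    intensities: pd.DataFrame  # index probe_id, one column per sample
    truth: GroundTruth

    def __iter__(self):
        return iter((self.annotation, self.intensities, self.truth))


def _random_energy_model(rng: np.random.Generator) -> EnergyModel:
    # centred stacking energies keep the typical 25-mer in the responsive
    # part of the Langmuir curve rather than saturating it
    lam = rng.uniform(-0.5, 0.5, 16)
    lam = lam - lam.mean()
    weights = rng.uniform(0.6, 1.4, N_STEPS)
    weights = weights / weights.mean()
    mm = lam + 2.0 + rng.normal(0.0, 0.2, 16)
    return EnergyModel(
        stacking=dict(zip(DINUCLEOTIDES, lam.tolist())),
        weights=weights,
        mismatch_stacking=dict(zip(DINUCLEOTIDES, mm.tolist())),
    )


def _smoothed_waves(rng, K: int, sd: float, span: int) -> np.ndarray:
    if sd == 0:
        return np.ones(K)
    z = rng.standard_normal(K + span)
    kernel = np.ones(span) / span
    smooth = np.convolve(z, kernel, mode="valid")[:K]
    smooth = smooth - smooth.mean()
    s = smooth.std()
    if s > 0:
        smooth = smooth * (sd / s)
    return np.exp(smooth)


def _place_segments(rng, cnv_spec, n_loci: int, gap: int = 6):
    """Non-overlapping locus-index segments for the requested CNVs."""
    spans = [(state, n, frac) for state, n, frac in cnv_spec]
    need = sum(n + gap for _, n, _ in spans)
    if need > n_loci:
        raise ConfigError(
            f"cnv_spec needs {need} loci (incl. spacing) but genome has {n_loci}"
        )
    placed = []  # (start_idx, end_idx exclusive, state, frac)
    taken = np.zeros(n_loci, dtype=bool)
    failed = False
    for state, n, frac in spans:
        for _ in range(1000):
            start = int(rng.integers(0, n_loci - n + 1))
            lo, hi = max(0, start - gap), min(n_loci, start + n + gap)
            if not taken[lo:hi].any():
                taken[start : start + n] = True
                placed.append((start, start + n, state, frac))
                break
        else:
            failed = True
            break
    if failed:
        # dense genomes defeat rejection sampling; pack the segments
        # sequentially instead (still deterministic given the seed)
        placed = []
        cursor = 0
        for state, n, frac in spans:
            if cursor + n > n_loci:
                raise ConfigError(
                    "could not place cnv_spec segments without overlap"
                )
            placed.append((cursor, cursor + n, state, frac))
            cursor += n + gap
    placed.sort()
    return placed


def _split_alleles(rng, cn: int) -> tuple[int, int]:
    """Uniform draw over integer compositions (n_A, n_B) with n_A+n_B=cn."""
    if cn == 0:
        return 0, 0
    n_a = int(rng.integers(0, cn + 1))
    return n_a, cn - n_a


def _random_mers(rng, n: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, 25))
    return ["".join(_BASES[row]) for row in idx]


#: maximum perfect-duplex binding energy accepted for a simulated probe;
#: 1.7 keeps the hybridized fraction above ~0.15 of a full site.  Array
#: designers likewise select probe sequences for adequate affinity, so
#: probes whose signal would drown in background never reach the chip.
MAX_PROBE_ENERGY = 1.7


def _screened_mer(rng, model: EnergyModel, variants=("",), max_tries: int = 200):
    """Draw a 25-mer whose match energy (for every central-base variant)
    stays below MAX_PROBE_ENERGY; falls back to the best draw seen."""
    best, best_e = None, np.inf
    for _ in range(max_tries):
        seq = _random_mers(rng, 1)[0]
        seqs = [
            seq if v == "" else seq[:12] + v + seq[13:] for v in variants
        ]
        e = max(probe_energies(model, seqs)[0])
        if e <= MAX_PROBE_ENERGY:
            return seq
        if e < best_e:
            best, best_e = seq, e
    return best


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate annotation, intensity matrix and ground truth for one cohort."""
    rng = np.random.default_rng(config.seed)
    model = _random_energy_model(rng)

    # ---- loci layout -------------------------------------------------
    n_main = config.n_snp_loci + config.n_np_loci
    K = n_main + config.n_chrx_loci
    is_np = np.zeros(K, dtype=bool)
    np_idx = rng.choice(n_main, size=config.n_np_loci, replace=False)
    is_np[np_idx] = True  # chrX extra loci are all SNP

    loci: list[tuple[str, str, int]] = []
    locus_type: list[str] = []
    for k in range(K):
        if k < n_main:
            chrom, pos = config.chrom, (k + 1) * config.locus_spacing_bp
        else:
            chrom, pos = "chrX", (k - n_main + 1) * config.locus_spacing_bp
        kind = "NP" if is_np[k] else "SNP"
        loci.append((f"{'NP' if is_np[k] else 'SNP'}_{k:06d}", chrom, pos))
        locus_type.append(kind)

    samples = [f"S{m:03d}" for m in range(config.n_samples)]
    M = config.n_samples
    males = set(range(config.n_male_samples))

    # ---- copy-number truth ------------------------------------------
    cn = np.full((K, M), 2, dtype=int)
    for k in range(n_main, K):
        for m in males:
            cn[k, m] = 1
    segments = _place_segments(rng, config.cnv_spec, n_main)
    calls: list[CNVCall] = []
    for start, stop, state, frac in segments:
        n_carriers = max(1, int(round(frac * M)))
        carriers = rng.choice(M, size=n_carriers, replace=False)
        for m in sorted(carriers):
            cn[start:stop, m] = state
            calls.append(
                CNVCall(
                    sample_id=samples[m],
                    chrom=config.chrom,
                    start=loci[start][2] - 1,
                    end=loci[stop - 1][2],
                    copy_state=state,
                    n_probes=stop - start,
                    mean_raw_cn=float(state),
                )
            )

    # ---- genotypes / allelic dosages --------------------------------
    dosage_a = np.zeros((K, M), dtype=int)
    dosage_b = np.zeros((K, M), dtype=int)
    p_a = 1.0 - config.maf
    for k in range(K):
        if locus_type[k] == "NP":
            dosage_a[k] = cn[k]
            continue
        for m in range(M):
            c = cn[k, m]
            if c == 2:
                # Hardy-Weinberg: two independent allele draws
                dosage_a[k, m] = int(rng.binomial(2, p_a))
            elif c == 1:
                dosage_a[k, m] = int(rng.binomial(1, p_a))
            else:
                dosage_a[k, m], _ = _split_alleles(rng, c)
            dosage_b[k, m] = c - dosage_a[k, m]

    # ---- amplification waves (identical across samples) -------------
    amplification = _smoothed_waves(
        rng, K, config.wave_sd, config.wave_correlation_span
    )

    # ---- probes ------------------------------------------------------
    records = []
    for k, (probeset_id, chrom, pos) in enumerate(loci):
        frag = f"frag{k // 4:05d}"
        if locus_type[k] == "NP":
            seq = _screened_mer(rng, model)
            records.append(
                (f"{probeset_id}_p0", probeset_id, "NP", seq, chrom, pos, frag)
            )
        else:
            n_a_probes = config.probes_per_snp - config.probes_per_snp // 2
            centers = rng.permutation(np.arange(4))[:2]
            variants = tuple(str(_BASES[c]) for c in centers)
            seqs = [
                _screened_mer(rng, model, variants) for _ in range(n_a_probes)
            ]
            for j, seq in enumerate(seqs):
                seq_a = seq[:12] + str(_BASES[centers[0]]) + seq[13:]
                records.append(
                    (f"{probeset_id}_A{j}", probeset_id, "A", seq_a, chrom, pos, frag)
                )
            for j in range(config.probes_per_snp // 2):
                seq_b = seqs[j % n_a_probes]
                seq_b = seq_b[:12] + str(_BASES[centers[1]]) + seq_b[13:]
                records.append(
                    (f"{probeset_id}_B{j}", probeset_id, "B", seq_b, chrom, pos, frag)
                )
    annotation = pd.DataFrame(
        records,
        columns=[
            "probe_id",
            "probeset_id",
            "target_allele",
            "sequence",
            "chrom",
            "position",
            "fragment_id",
        ],
    )

    # ---- intensities -------------------------------------------------
    e_match, e_mismatch = probe_energies(model, annotation["sequence"].tolist())
    lf = lambda e: expit(-e)
    probe_locus = np.array(
        [int(pid.split("_")[1]) for pid in annotation["probeset_id"]]
    )
    allele = annotation["target_allele"].to_numpy()
    fa = np.where(allele == "B", lf(e_mismatch), lf(e_match))
    fb = np.where(allele == "B", lf(e_match), lf(e_mismatch))
    fa = np.where(allele == "NP", lf(e_match), fa)
    fb = np.where(allele == "NP", 0.0, fb)

    signal = (
        dosage_a[probe_locus, :] * fa[:, None]
        + dosage_b[probe_locus, :] * fb[:, None]
    )
    signal *= amplification[probe_locus, None]
    noise = (
        rng.normal(0.0, config.noise_sd, size=signal.shape)
        if config.noise_sd > 0
        else 0.0
    )
    intens = np.maximum(signal + config.background_mean + noise, 0.0)
    intensities = pd.DataFrame(
        intens, index=pd.Index(annotation["probe_id"], name="probe_id"), columns=samples
    )

    truth = GroundTruth(
        loci=loci,
        locus_type=locus_type,
        samples=samples,
        cn=cn,
        dosage_a=dosage_a,
        dosage_b=dosage_b,
        amplification=amplification,
        energy_model=model,
        calls=calls,
    )
    return SimulatedDataset(annotation=annotation, intensities=intensities, truth=truth)


# ---------------------------------------------------------------------------
# fixture round trip
# ---------------------------------------------------------------------------

FIXTURE_FILES = (
    "probes.tsv",
    "intensities.tsv",
    "truth_cn.tsv",
    "truth_calls.tsv",
    "energy_model.json",
)


def write_fixtures(dataset: SimulatedDataset, directory) -> dict:
    """Write the dataset as plain-text fixtures plus a checksum manifest.

    Files: probe annotation TSV, intensity TSV, two truth TSVs (per-locus
    copy/dosage grid with amplification factors; embedded calls) and the
    generating energy model as JSON.  Returns the manifest (also written to
    ``manifest.json``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = dataset.truth

    dataset.annotation.to_csv(directory / "probes.tsv", sep="\t", index=False)
    dataset.intensities.to_csv(directory / "intensities.tsv", sep="\t")

    cn_df = pd.DataFrame(
        {
            "probeset_id": [pid for pid, _, _ in t.loci],
            "chrom": [c for _, c, _ in t.loci],
            "position": [p for _, _, p in t.loci],
            "locus_type": t.locus_type,
            "amp_factor": t.amplification,
        }
    )
    for j, s in enumerate(t.samples):
        cn_df[f"cn_{s}"] = t.cn[:, j]
        cn_df[f"na_{s}"] = t.dosage_a[:, j]
        cn_df[f"nb_{s}"] = t.dosage_b[:, j]
    cn_df.to_csv(directory / "truth_cn.tsv", sep="\t", index=False)

    calls_df = pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.start, c.end, c.copy_state, c.n_probes)
            for c in t.calls
        ],
        columns=["sample_id", "chrom", "start", "end", "copy_state", "n_probes"],
    )
    calls_df.to_csv(directory / "truth_calls.tsv", sep="\t", index=False)

    t.energy_model.to_json(directory / "energy_model.json")

    manifest = {
        "files": {
            name: hashlib.sha256((directory / name).read_bytes()).hexdigest()
            for name in FIXTURE_FILES
        }
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def load_fixtures(directory) -> SimulatedDataset:
    """Read back fixtures written by :func:`write_fixtures`."""
    directory = Path(directory)
    annotation = pd.read_csv(directory / "probes.tsv", sep="\t")
    intensities = pd.read_csv(directory / "intensities.tsv", sep="\t", index_col=0)
    cn_df = pd.read_csv(directory / "truth_cn.tsv", sep="\t")
    calls_df = pd.read_csv(directory / "truth_calls.tsv", sep="\t")
    model = EnergyModel.from_json(directory / "energy_model.json")

    samples = list(intensities.columns)
    loci = list(
        zip(cn_df["probeset_id"], cn_df["chrom"], cn_df["position"].astype(int))
    )
    truth = GroundTruth(
        loci=loci,
        locus_type=list(cn_df["locus_type"]),
        samples=samples,
        cn=cn_df[[f"cn_{s}" for s in samples]].to_numpy(dtype=int),
        dosage_a=cn_df[[f"na_{s}" for s in samples]].to_numpy(dtype=int),
        dosage_b=cn_df[[f"nb_{s}" for s in samples]].to_numpy(dtype=int),
        amplification=cn_df["amp_factor"].to_numpy(dtype=float),
        energy_model=model,
        calls=[
            CNVCall(
                sample_id=r.sample_id,
                chrom=r.chrom,
                start=int(r.start),
                end=int(r.end),
                copy_state=int(r.copy_state),
                n_probes=int(r.n_probes),
                mean_raw_cn=float(r.copy_state),
            )
            for r in calls_df.itertuples()
        ],
    )
    return SimulatedDataset(annotation=annotation, intensities=intensities, truth=truth)
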