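"""End-to-end orchestration: estimate -> normalize -> calibrate -> segment.

The pipeline reads a probe annotation and an intensity matrix, estimates
allelic concentrations per sample, median-normalizes arrays, calibrates
per-locus amplification against a reference pool, segments each calibrated
track with the distance-aware HMM and writes all artifacts plus a run
manifest.  Deterministic given inputs and seed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as wio
from .ac_estimation import estimate_sample
from .errors import ConfigError, WavecnvError
from .normalization import (
    ConcentrationMatrix,
    calibrate,
    fit_adjustment_factors,
    normalize_arrays,
    tracks_from_matrix,
)
from .probe_model import EnergyModel, train_energy_model
from .segmentation import HMMParameters, segment_track

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and knobs of one pipeline run."""

    probe_annotation: str
    intensities: str
    output_dir: str
    energy_model: str | None = None  # trained from the first sample if absent
    reference_samples: list[str] | None = None  # default: all samples
    hmm_overrides: dict = field(default_factory=dict)
    min_probes: int = 5
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        for p in (self.probe_annotation, self.intensities):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.energy_model is not None and not Path(self.energy_model).exists():
            raise ConfigError(f"energy model path does not exist: {self.energy_model}")
        unknown = set(self.hmm_overrides) - set(HMMParameters().to_dict())
        if unknown:
            raise ConfigError(f"unknown HMM parameter override(s): {sorted(unknown)}")


@dataclass
class PipelineResult:
    calls: list
    tracks: dict
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; see module docstring.

    Raises a :class:`~wavecnv.errors.WavecnvError` subclass on any stage
    failure (the CLI maps that to a nonzero exit status with the stage name).
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    stage = "read-inputs"
    try:
        probesets = wio.read_probe_annotation(config.probe_annotation)
        intensities = wio.read_intensity_matrix(config.intensities)
        samples = list(intensities.columns)

        stage = "energy-model"
        if config.energy_model is not None:
            model = EnergyModel.from_json(config.energy_model)
        else:
            logger.info("no energy model given; training from sample %s", samples[0])
            probes = [p for ps in probesets for p in ps.probes]
            model = train_energy_model(intensities[samples[0]], probes)
            model.to_json(outdir / "energy_model.json")
            written.append("energy_model.json")

        stage = "estimate"
        loci = None
        columns = []
        for s in samples:
            estimates = estimate_sample(
                probesets, intensities[s], model, sample_id=s
            )
            sample_loci = [(e.probeset_id, e.chrom, e.position) for e in estimates]
            if loci is None:
                loci = sample_loci
            elif sample_loci != loci:
                raise ConfigError(
                    f"sample {s}: probeset failures differ between samples; "
                    "cannot assemble a rectangular concentration matrix"
                )
            columns.append([e.N_total for e in estimates])
            fname = f"concentrations_{s}.tsv"
            wio.write_concentrations(estimates, outdir / fname)
            written.append(fname)
        matrix = ConcentrationMatrix(
            loci=loci, samples=samples, values=np.array(columns).T
        )

        stage = "normalize"
        normalized, norm_factors = normalize_arrays(matrix)

        stage = "calibrate"
        reference = config.reference_samples or samples
        missing = sorted(set(reference) - set(samples))
        if missing:
            raise ConfigError(f"reference samples not in matrix: {missing}")
        factors = fit_adjustment_factors(normalized.subset_samples(reference))
        wio.write_adjustment_factors(factors, outdir / "adjustment_factors.tsv")
        written.append("adjustment_factors.tsv")
        tracks = {}
        for track in tracks_from_matrix(normalized):
            cal = calibrate(track, factors)
            tracks[track.sample_id] = cal
            for ext, writer in (
                ("bedgraph", wio.write_track_bedgraph),
                ("tsv", wio.write_track_tsv),
            ):
                fname = f"raw_cn_{track.sample_id}.{ext}"
                writer(cal, outdir / fname)
                written.append(fname)

        stage = "segment"
        params = HMMParameters.from_dict(
            {**HMMParameters().to_dict(), **config.hmm_overrides}
        )
        all_calls = []
        for s in samples:
            calls, _ = segment_track(
                tracks[s], params, min_probes=config.min_probes
            )
            all_calls.extend(calls)
        wio.write_calls(all_calls, outdir / "calls.tsv")
        written.append("calls.tsv")
    except WavecnvError:
        logger.error("pipeline failed at stage %r", stage)
        raise

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": len(samples),
        "n_probesets": len(probesets),
        "reference_samples": list(reference),
        "files": sorted(written),
    }
    wio.write_json(manifest, outdir / "run_manifest.json")
    logger.info("pipeline complete: %d call(s) across %d sample(s)",
                len(all_calls), len(samples))
    return PipelineResult(calls=all_calls, tracks=tracks, manifest=manifest)
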