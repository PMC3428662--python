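"""Shared fixtures: small simulated cohorts and pipeline helpers."""

import warnings

import numpy as np
import pytest

import wavecnv as w


def run_preprocessing(dataset, reference=None):
    """estimate -> normalize -> calibrate for a simulated dataset.

    Returns (normalized tracks dict, calibrated tracks dict, matrix).
    """
    probesets = w.probesets_from_frame(dataset.annotation)
    model = dataset.truth.energy_model
    columns, loci = [], None
    for s in dataset.truth.samples:
        est = w.estimate_sample(
            probesets, dataset.intensities[s], model, sample_id=s
        )
        loci = [(e.probeset_id, e.chrom, e.position) for e in est]
        columns.append([e.N_total for e in est])
    matrix = w.ConcentrationMatrix(
        loci=loci, samples=dataset.truth.samples, values=np.array(columns).T
    )
    normalized, _ = w.normalize_arrays(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pool = (
            normalized.subset_samples(reference) if reference else normalized
        )
        factors = w.fit_adjustment_factors(pool)
    norm_tracks = {t.sample_id: t for t in w.tracks_from_matrix(normalized)}
    cal_tracks = {
        sid: w.calibrate(t, factors) for sid, t in norm_tracks.items()
    }
    return norm_tracks, cal_tracks, matrix


def pooled_call_counts(pred_calls, truth_calls, samples):
    """Sum support/recovery counts over samples (pooled precision/recall)."""
    n_pred = n_sup = n_true = n_rec = 0
    for s in samples:
        p = [w.Region(c.chrom, c.start, c.end) for c in pred_calls if c.sample_id == s]
        t = [w.Region(c.chrom, c.start, c.end) for c in truth_calls if c.sample_id == s]
        if not p and not t:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            r = w.precision_recall(p, t)
        n_pred += r.n_predicted
        n_sup += r.n_supported
        n_true += r.n_true
        n_rec += r.n_recovered
    return n_pred, n_sup, n_true, n_rec


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless cohort without CNVs or waves."""
    cfg = w.SimulationConfig(
        seed=2,
        n_snp_loci=120,
        n_np_loci=30,
        n_samples=8,
        noise_sd=0.0,
        wave_sd=0.0,
        cnv_spec=[],
    )
    return w.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default seeded scenario: 20 samples, waves, noise, planted CNVs."""
    return w.simulate_dataset(w.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_probesets(default_dataset):
    return w.probesets_from_frame(default_dataset.annotation)
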