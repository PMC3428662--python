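"""Suppressing genomic waves with a reference-pool calibration.

Simulates a cohort with locus-stable amplification waves (log-sd 0.3),
normalizes each array to median 2 and calibrates each locus by the pool
median.  The within-sample variance of the raw CN track collapses.
"""

import numpy as np

from wavecnv import (
    ConcentrationMatrix,
    SimulationConfig,
    calibrate,
    estimate_sample,
    fit_adjustment_factors,
    normalize_arrays,
    probesets_from_frame,
    simulate_dataset,
    tracks_from_matrix,
)

ds = simulate_dataset(
    SimulationConfig(
        seed=4, n_snp_loci=300, n_np_loci=60, n_samples=20,
        wave_sd=0.3, cnv_spec=[],
    )
)
probesets = probesets_from_frame(ds.annotation)
columns, loci = [], None
for s in ds.truth.samples:
    est = estimate_sample(
        probesets, ds.intensities[s], ds.truth.energy_model, sample_id=s
    )
    loci = [(e.probeset_id, e.chrom, e.position) for e in est]
    columns.append([e.N_total for e in est])
matrix = ConcentrationMatrix(
    loci=loci, samples=ds.truth.samples, values=np.array(columns).T
)

normalized, _ = normalize_arrays(matrix)
factors = fit_adjustment_factors(normalized)

for track in tracks_from_matrix(normalized)[:5]:
    before = np.var(track.values, ddof=1)
    after = np.var(calibrate(track, factors).values, ddof=1)
    print(
        f"{track.sample_id}: variance {before:.4f} -> {after:.4f} "
        f"({before / after:.1f}x reduction)"
    )
print(
    "The waves are identical across arrays, so dividing every locus by the"
    " pool median removes them without touching real copy-number signal."
)
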