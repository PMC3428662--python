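"""The whole tool end to end, through files and the pipeline entry point.

Writes a simulated cohort to disk, runs estimate -> normalize -> calibrate ->
segment, and scores the resulting calls against the planted truth.
"""

import tempfile
from pathlib import Path

from wavecnv import (
    PipelineConfig,
    Region,
    SimulationConfig,
    precision_recall,
    run_pipeline,
    simulate_dataset,
    write_fixtures,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    ds = simulate_dataset(SimulationConfig(seed=6))
    write_fixtures(ds, tmp / "fixtures")

    result = run_pipeline(
        PipelineConfig(
            probe_annotation=str(tmp / "fixtures" / "probes.tsv"),
            intensities=str(tmp / "fixtures" / "intensities.tsv"),
            energy_model=str(tmp / "fixtures" / "energy_model.json"),
            output_dir=str(tmp / "out"),
        )
    )

    n_pred = n_sup = n_true = n_rec = 0
    for s in ds.truth.samples:
        pred = [
            Region(c.chrom, c.start, c.end)
            for c in result.calls
            if c.sample_id == s
        ]
        true = [
            Region(c.chrom, c.start, c.end)
            for c in ds.truth.calls
            if c.sample_id == s
        ]
        if not pred and not true:
            continue
        r = precision_recall(pred, true)
        n_pred += r.n_predicted
        n_sup += r.n_supported
        n_true += r.n_true
        n_rec += r.n_recovered

    print(f"calls: {len(result.calls)}  truth segments: {len(ds.truth.calls)}")
    print(f"precision: {n_sup}/{n_pred} = {100 * n_sup / n_pred:.2f}%")
    print(f"recall:    {n_rec}/{n_true} = {100 * n_rec / n_true:.2f}%")
    print(
        "A predicted call counts as supported when >50% of either region"
        " is covered by the other."
    )
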