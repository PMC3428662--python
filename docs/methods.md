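# Methods

## Hybridization model

A 25-mer oligonucleotide probe binds its target following a Langmuir-like
adsorption law: the occupied fraction of probe sites at binding free energy
`E` is `θ(E) = 1/(1+exp(E))`, strictly decreasing in `E`. The energy is a
position-dependent nearest-neighbor (PDNN) sum over the 24 dinucleotide
steps, `E = Σ ω_i λ(b_i, b_{i+1})`. Probe length is fixed at 25 (so exactly
24 steps); other lengths are rejected at input validation.

At a polymorphic locus both alleles bind every probe. The matched allele
forms a perfect duplex; the off-target allele forms a duplex mismatched at
the interrogated central base (position 13), modelled by replacing the two
steps touching that base (steps 12 and 13) with entries from a separate
mismatch stacking table. This localizes the mismatch effect, keeps the
energy linear in the tabulated constants, and leaves untrained models with
a sensible default (mismatch table = stacking + 2.0, which suppresses the
off-target Langmuir fraction by roughly e⁴ for typical weights).

Identifiability: `(ω, λ)` are only determined up to the scale swap
`(ω/c, λ·c)`; we fix `mean(ω) = 1` and leave `λ` free. The background
intensity `I_bg` carries no sequence model of its own — it is absorbed as a
per-probeset intercept during estimation.

### Single-array training

`train_energy_model` fits `(ω, λ, mismatch λ)` from one array by
alternating (a) per-probeset unconstrained OLS of `(N_A, N_B, I_bg)` given
the energies with (b) a damped (Levenberg–Marquardt) least-squares update
of the energy constants. Step (b) profiles the concentrations into the
residual (variable projection): each trial energy vector is scored at its
own optimal concentrations, which is the fixed point plain alternation
converges to, reached in far fewer sweeps. The Jacobian holds the profiled
concentrations fixed (Kaufman simplification). Two numerical choices
stabilize the fit: `ω` is carried on the log scale (positivity is
structural, and sign-flip local traps disappear), and a warm-up pass fits
the two stacking tables at flat weights before releasing everything. After
each sweep `ω` is renormalized to mean 1 with the compensating rescale of
both tables (objective unchanged). Iteration stops when the relative
objective decrease falls below `tol`; three consecutive non-decreasing
sweeps raise a convergence error that carries the best model seen.

Only SNP probesets with probes for both alleles enter the fit — a
single-probe nonpolymorphic (NP) probeset cannot separate signal from
background. Fewer than 500 usable probesets triggers a warning: on
noiseless data 500 probesets recover the generating constants to machine
precision, but under realistic probe noise the constants are only weakly
identified at this scale (hundreds of probesets); on a real array with
~10⁵ probesets the same estimator sharpens by two orders of magnitude.
Training is deterministic given the initial model (default: flat weights,
zero stacking, +2.0 mismatch penalty).

## Concentration estimation

For each probeset and sample, the design matrix has one row per probe:
`[θ(E_A), θ(E_B), 1]` for SNP probesets (an A-probe's `E_A` is its match
energy and `E_B` its central-mismatch energy; B-probes the converse) and
`[θ(E), 1]` for NP probesets. Ordinary least squares gives
`(N_A, N_B, I_bg)`; cross-hybridization is part of the design, not a bias.
Negative concentration coefficients are truncated to zero after the
unconstrained solve and flagged (`clipped`), preserving the linear
estimator while letting downstream consumers filter. `residual_sd` is
`sqrt(RSS/(n−p))` when `n > p`.

A single-probe NP probeset cannot support two parameters. Its background is
fixed to a per-array constant: the **median of the per-SNP-probeset OLS
background estimates** from the same array. This estimator is exact on
noiseless data and robust under noise; the often-used alternative (median
of the lowest intensity decile) is biased upward by the residual specific
signal of low-affinity probes, which can push the weakest NP loci to clip
at zero on every sample and poison the per-locus calibration. The
lowest-decile rule remains as a fallback for arrays without SNP probesets.

Failed probesets (rank-deficient or underdetermined designs) are skipped
with one warning per sample; more than 50% failures aborts the sample.

## Normalization and wave calibration

Arrays are made comparable by `α_m = 2/median_k(N_mk)`; the per-sample
median of the output is exactly 2 (up to floating-point rounding — a few
ulp, since even `3·(2/3)` is not bit-exact in IEEE arithmetic). Medians of
even-length samples use the midpoint of the two central order statistics.

Per-locus amplification efficiencies (genomic waves) are stable across
arrays, so `γ_k = 2/median_m(N'_mk)` over a reference pool of `M` arrays
cancels them: `N̂_mk = N'_mk·γ_k`. The hard floor is `M ≥ 3` with a warning
below 10. CNV contamination of the pool is tolerated — the median ignores
carriers as long as they are a minority at any locus — and no outlier
trimming is applied. The diploid target constant 2 is fixed; mixed-sex
pools on sex chromosomes are the caller's responsibility (calibrate chrX
against a diploid-X pool, as the acceptance script does). `α` is computed
over all loci present in the input.

## Segmentation

Hidden states are the true copy numbers {0, 1, 2, 3, ≥4}; state "≥4" emits
a normal centred at 4 and higher values are not truncated. Emissions are
Gaussian with shared standard deviation (default 0.4, floor 0.05); the HMM
runs on the linear raw-CN scale so the state means are the copy numbers
themselves. Transitions blend identity with a base matrix by
`f = 1−exp(−d/D)`: `A(d) = (1−f)I + fB`. The base matrix makes leaving the
diploid state rare (10⁻⁴ per step) and returning likely (0.05); `D`
defaults to 100 kb, putting the array's typical inter-locus gaps (a few kb)
deep in the "linked" regime. The functional form was chosen for its
testable limits: `A→I` as `d→0`, `A→B` as `d→∞`, rows always sum to 1.

Decoding is exact Viterbi in log space; exact ties break toward the lower
copy state, so deletions win ties against amplifications
(deterministic). Parameter refinement is Viterbi training (hard EM) rather
than Baum–Welch: decode, re-estimate the shared emission sd (pooled
deviation from the decoded means, capped at the nearest-state deviation so
an oversmoothed path cannot inflate the width it is re-decoded with) and
the base transition matrix (+1 Laplace-smoothed counts), repeat until the
path repeats or `max_iter` (20). State means and `D` are never
re-estimated — they anchor the states. Chromosomes are segmented
independently, each starting from the initial distribution (heavily
weighted on diploid).

Maximal non-diploid runs become calls with 0-based half-open coordinates
(`[first position − 1, last position)`); runs under `min_probes` (default
5) are below the array's design resolution and are dropped.

## Evaluation

Two regions are concordant when **more than** 50% of either is covered by
the other; exactly half does not match (strict inequality, documented
boundary). Precision counts predicted regions concordant with ≥1 truth
region; recall counts truth regions concordant with ≥1 prediction; empty
sets leave the ratio undefined (NaN with a warning). The batch-stability
ratio clusters the regions of all call sets by single linkage under the
same concordance relation: U = clusters, I = clusters containing a region
from every set. Clusters (not base pairs) are counted because per-batch
call sets are small and the ratio compares whole events. The
sex-classification AUC uses the rank (Mann–Whitney) formula with ties
counted ½, identical to threshold-sweeping on the raw CN. Track variance
first rescales the track median to a stated target (2 diploid, 1 haploid)
and uses the n−1 denominator. Reported percentages and ratios round
half-up to 2 decimals.

## Simulator

The generator emulates exactly the assumptions above: random 25-mer probes
(3 A- + 3 B-probes per SNP, one probe per NP locus), Hardy–Weinberg
genotypes at a configurable allele frequency, integer CN ground truth with
planted segments (copy number split uniformly over integer allelic
compositions), per-locus amplification factors `exp(moving-average-smoothed
Gaussian)` **identical across samples**, intensity = amplification ×
Langmuir signal + background + Gaussian noise truncated at zero, and
optionally a haploid-X male cohort. Two realism choices matter:

* stacking energies are centred and probe sequences are rejection-sampled
  to a maximum perfect-duplex energy (1.7, hybridized fraction ≥ ~0.15) —
  array designers likewise select probes for adequate affinity, and
  unselected random probes occasionally have so little signal that their
  loci degenerate to zero across the cohort;
* the default probe noise (sd 0.05) is anchored to the raw-CN dispersion
  reported for well-behaved real arrays (calibrated track variances of
  roughly 0.03–0.11, i.e. sd ≈ 0.17–0.33): it yields diploid-region raw-CN
  sd ≈ 0.22–0.26 at desk scale.

What the simulator does **not** emulate: restriction-fragment structure and
PCR chemistry (waves are drawn, not mechanistic), GC-content correlation of
the waves, probe-level outliers and spatial artifacts, linkage
disequilibrium between SNPs, and inherited (trio) CNV structure. Passing
tests therefore demonstrate correctness of the estimators and the
segmentation under the stated model, not robustness to every artifact of
real arrays.

Default study conditions: 800 SNP + 200 NP loci at 3 kb spacing on one
chromosome, 20 samples, waves with log-sd 0.3 smoothed over 15 loci,
background 0.5, and four planted CNV classes (12-locus deletions CN 1 and
duplications CN 3 in 30% of samples; 10-locus CN 0 and CN 4 events in
15%). Same config and seed give byte-identical fixtures; the five fixture
files are checksummed in a manifest.

## Problem sizes

The test suite and the acceptance script run cohorts of 150–1000 loci and
6–45 samples, with 500-probeset training arrays — sizes at which every
stage's contract (exact noiseless recovery, unbiasedness, wave
suppression, ≥0.90 end-to-end precision/recall, batch stability) is
measurable in seconds to a couple of minutes while remaining faithful to
the per-locus and per-probeset structure of the full-size problem.

## Known limitations

* Single-array energy training is weakly identified under noise at
  hundreds of probesets (see above); between-array stability of the
  constants is demonstrated on noiseless arrays.
* The calibration cannot correct batch effects *within* the reference pool
  itself (pools processed under different conditions bias `γ_k`), and very
  small pools make `γ_k` the dominant noise source.
* Allele-specific CNV states and genotype calling from `(N_A, N_B)` are out
  of scope; the HMM sees total copy number only.
* CNVs shared by ≥50% of the reference pool at a locus defeat the median
  calibration there.
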