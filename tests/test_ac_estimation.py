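"""Allelic-concentration OLS: design, recovery, unbiasedness, cross-hyb."""

import warnings

import numpy as np
import pytest

import wavecnv as w
from wavecnv.ac_estimation import array_background
from wavecnv.errors import (
    SampleQualityError,
    SingularDesignError,
    UnderdeterminedError,
)
from wavecnv.probe_model import DINUCLEOTIDES, EnergyModel, ProbeRecord


def make_snp_probeset(rng, probeset_id="ps1", n_pairs=3, chrom="chr1", position=1000):
    bases = list("ACGT")
    probes = []
    for j in range(n_pairs):
        seq = "".join(rng.choice(bases, 25))
        probes.append(
            ProbeRecord(
                f"{probeset_id}_A{j}", probeset_id, "A",
                seq[:12] + "A" + seq[13:], chrom, position, "f0",
            )
        )
        probes.append(
            ProbeRecord(
                f"{probeset_id}_B{j}", probeset_id, "B",
                seq[:12] + "C" + seq[13:], chrom, position, "f0",
            )
        )
    return w.Probeset(probeset_id, "SNP", probes, chrom, position)


def make_model(rng):
    lam = rng.uniform(-0.4, 0.4, 16)
    lam -= lam.mean()
    weights = rng.uniform(0.7, 1.3, 24)
    weights /= weights.mean()
    return EnergyModel(
        stacking=dict(zip(DINUCLEOTIDES, lam)),
        weights=weights,
        mismatch_stacking=dict(zip(DINUCLEOTIDES, lam + 2.0)),
    )


def noiseless_intensities(probeset, model, n_a, n_b, bg):
    X = w.design_matrix(probeset, model)
    if probeset.locus_type == "SNP":
        return X @ np.array([n_a, n_b, bg])
    return X @ np.array([n_a, bg])


class TestDesignMatrix:
    def test_zero_energy_rows(self):
        rng = np.random.default_rng(0)
        ps = make_snp_probeset(rng)
        flat = EnergyModel(
            stacking={d: 0.0 for d in DINUCLEOTIDES},
            weights=np.ones(24),
            mismatch_stacking={d: 0.0 for d in DINUCLEOTIDES},
        )
        X = w.design_matrix(ps, flat)
        np.testing.assert_allclose(X[:, 0], 0.5)
        np.testing.assert_allclose(X[:, 1], 0.5)
        np.testing.assert_allclose(X[:, 2], 1.0)

    def test_rows_match_componentwise_calls(self):
        """Compositional oracle: each row rebuilt from binding_energy +
        langmuir_fraction directly."""
        rng = np.random.default_rng(1)
        model = make_model(rng)
        ps = make_snp_probeset(rng)
        X = w.design_matrix(ps, model)
        for row, probe in zip(X, ps.probes):
            e_match = w.binding_energy(model, probe.sequence, False)
            e_mm = w.binding_energy(model, probe.sequence, True)
            if probe.target_allele == "A":
                ea, eb = e_match, e_mm
            else:
                ea, eb = e_mm, e_match
            assert row[0] == pytest.approx(w.langmuir_fraction(ea), abs=1e-12)
            assert row[1] == pytest.approx(w.langmuir_fraction(eb), abs=1e-12)
            assert row[2] == 1.0


class TestEstimateProbeset:
    @pytest.mark.parametrize("n_a,n_b", [(2.0, 0.0), (1.0, 1.0), (0.0, 2.0)])
    def test_noiseless_exact_recovery(self, n_a, n_b):
        rng = np.random.default_rng(2)
        model = make_model(rng)
        ps = make_snp_probeset(rng)
        y = noiseless_intensities(ps, model, n_a, n_b, 50.0)
        est = w.estimate_probeset(ps, y, model)
        assert est.N_A == pytest.approx(n_a, abs=1e-8)
        assert est.N_B == pytest.approx(n_b, abs=1e-8)
        assert est.background == pytest.approx(50.0, abs=1e-7)
        assert est.N_total == pytest.approx(est.N_A + est.N_B)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            model = make_model(rng)
            ps = make_snp_probeset(rng, n_pairs=4)
            y = noiseless_intensities(
                ps, model, *rng.uniform(0.5, 3.0, 2), rng.uniform(0, 20)
            ) + rng.normal(0, 0.3, 8)
            X = w.design_matrix(ps, model)
            beta = np.linalg.inv(X.T @ X) @ X.T @ y
            est = w.estimate_probeset(ps, y, model)
            if not est.clipped:
                assert est.N_A == pytest.approx(beta[0], abs=1e-8)
                assert est.N_B == pytest.approx(beta[1], abs=1e-8)
            assert est.background == pytest.approx(beta[2], abs=1e-8)

    def test_negative_coefficients_clip_and_flag(self):
        rng = np.random.default_rng(4)
        model = make_model(rng)
        ps = make_snp_probeset(rng)
        # strong noise pattern pushing one allele negative
        y = noiseless_intensities(ps, model, 2.0, 0.0, 1.0)
        y -= 3.0 * w.design_matrix(ps, model)[:, 1]  # subtract B-column signal
        est = w.estimate_probeset(ps, y, model)
        assert est.clipped
        assert est.N_B == 0.0

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(5)
        model = make_model(rng)
        ps = make_snp_probeset(rng)
        y = noiseless_intensities(ps, model, 1.3, 0.9, 4.0) + rng.normal(0, 0.1, 6)
        est = w.estimate_probeset(ps, y, model)
        order = rng.permutation(6)
        shuffled = w.Probeset(
            ps.probeset_id, "SNP", [ps.probes[i] for i in order],
            ps.chrom, ps.position,
        )
        est2 = w.estimate_probeset(shuffled, y[order], model)
        assert est2.N_A == pytest.approx(est.N_A, abs=1e-10)
        assert est2.N_B == pytest.approx(est.N_B, abs=1e-10)

    def test_identical_probes_are_singular(self):
        rng = np.random.default_rng(6)
        model = make_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 25))
        probes = [
            ProbeRecord(f"p{i}", "ps", "A" if i < 2 else "B", seq, "chr1", 5, "f")
            for i in range(4)
        ]
        ps = w.Probeset("ps", "SNP", probes, "chr1", 5)
        with pytest.raises(SingularDesignError):
            w.estimate_probeset(ps, [1.0, 1.0, 1.0, 1.0], model)

    def test_single_probe_np_needs_background(self):
        rng = np.random.default_rng(7)
        model = make_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 25))
        ps = w.Probeset(
            "np1", "NP", [ProbeRecord("np1_p0", "np1", "NP", seq, "chr1", 9, "f")],
            "chr1", 9,
        )
        with pytest.raises(UnderdeterminedError):
            w.estimate_probeset(ps, [3.0], model)
        frac = w.langmuir_fraction(w.binding_energy(model, seq))
        est = w.estimate_probeset(ps, [2 * frac + 0.5], model, fixed_background=0.5)
        assert est.N_A == pytest.approx(2.0, abs=1e-10)

    def test_mean_unbiased_over_replicates(self):
        """Across >= 500 noisy replicates the mean estimate sits within 3
        standard errors of the generating concentration."""
        rng = np.random.default_rng(8)
        model = make_model(rng)
        ps = make_snp_probeset(rng)
        n_a, n_b, bg = 1.0, 1.0, 5.0
        clean = noiseless_intensities(ps, model, n_a, n_b, bg)
        reps = 600
        ests = np.empty(reps)
        for i in range(reps):
            y = clean + rng.normal(0, 0.1, clean.size)
            ests[i] = w.estimate_probeset(ps, y, model).N_A
        se = ests.std(ddof=1) / np.sqrt(reps)
        assert abs(ests.mean() - n_a) < 3 * se

    def test_cross_hyb_model_beats_naive_in_mean(self):
        """With off-target binding simulated, the two-allele design has mean
        absolute N_total error no larger than a match-column-only fit."""
        rng = np.random.default_rng(9)
        model = make_model(rng)
        errs_full, errs_naive = [], []
        for _ in range(120):
            ps = make_snp_probeset(rng)
            n_a, n_b = 2.0, 0.0  # homozygote: cross-hyb hits the B probes
            clean = noiseless_intensities(ps, model, n_a, n_b, 2.0)
            y = clean + rng.normal(0, 0.05, clean.size)
            est = w.estimate_probeset(ps, y, model)
            errs_full.append(abs(est.N_total - (n_a + n_b)))
            # naive: each probe regressed on its match column + intercept only
            X = w.design_matrix(ps, model)
            is_a = np.array([p.target_allele == "A" for p in ps.probes])
            match = np.where(is_a, X[:, 0], X[:, 1])
            Xn = np.column_stack([match, np.ones(len(y))])
            coef, *_ = np.linalg.lstsq(Xn, y, rcond=None)
            errs_naive.append(abs(coef[0] - (n_a + n_b)))
        assert np.mean(errs_full) <= np.mean(errs_naive)


class TestEstimateSample:
    def test_genome_ordering(self, noiseless_dataset):
        ds = noiseless_dataset
        probesets = w.probesets_from_frame(ds.annotation)
        est = w.estimate_sample(
            probesets, ds.intensities["S000"], ds.truth.energy_model
        )
        keys = [(e.chrom, e.position) for e in est]
        assert keys == sorted(keys)
        assert len(est) == len(probesets)

    def test_noiseless_sample_recovers_truth(self, noiseless_dataset):
        ds = noiseless_dataset
        probesets = w.probesets_from_frame(ds.annotation)
        est = w.estimate_sample(
            probesets, ds.intensities["S003"], ds.truth.energy_model,
            sample_id="S003",
        )
        idx = {pid: k for k, (pid, _, _) in enumerate(ds.truth.loci)}
        j = ds.truth.samples.index("S003")
        errors = [
            abs(e.N_total - ds.truth.cn[idx[e.probeset_id], j]) for e in est
        ]
        assert max(errors) < 1e-6

    def test_singular_probeset_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(10)
        model = make_model(rng)
        good = [make_snp_probeset(rng, f"ok{i}", position=100 * (i + 1))
                for i in range(4)]
        seq = "".join(rng.choice(list("ACGT"), 25))
        dup_probes = [
            ProbeRecord(f"d{i}", "dup", "A" if i < 2 else "B", seq, "chr1", 999, "f")
            for i in range(4)
        ]
        bad = w.Probeset("dup", "SNP", dup_probes, "chr1", 999)
        intens = {}
        for ps in good:
            y = noiseless_intensities(ps, model, 1, 1, 2.0)
            intens.update({p.probe_id: v for p, v in zip(ps.probes, y)})
        intens.update({p.probe_id: 1.0 for p in dup_probes})
        import logging

        with caplog.at_level(logging.WARNING, logger="wavecnv.ac_estimation"):
            est = w.estimate_sample(good + [bad], intens, model, sample_id="s")
        assert len(est) == 4
        assert "dup" not in {e.probeset_id for e in est}
        assert any("skipped" in r.message for r in caplog.records)

    def test_majority_failures_abort_sample(self):
        rng = np.random.default_rng(11)
        model = make_model(rng)
        seq = "".join(rng.choice(list("ACGT"), 25))
        bad_sets = []
        for i in range(3):
            probes = [
                ProbeRecord(f"b{i}_{j}", f"bad{i}", "A" if j < 2 else "B",
                            seq, "chr1", 10 + i, "f")
                for j in range(4)
            ]
            bad_sets.append(w.Probeset(f"bad{i}", "SNP", probes, "chr1", 10 + i))
        ok = make_snp_probeset(rng, "ok", position=500)
        intens = {p.probe_id: 1.0 for ps in bad_sets for p in ps.probes}
        y = noiseless_intensities(ok, model, 1, 1, 2.0)
        intens.update({p.probe_id: v for p, v in zip(ok.probes, y)})
        with pytest.raises(SampleQualityError):
            w.estimate_sample(bad_sets + [ok], intens, model)


def test_fallback_background_is_low_decile_median():
    rng = np.random.default_rng(12)
    ps = make_snp_probeset(rng, "only")
    intens = {p.probe_id: float(i + 1) for i, p in enumerate(ps.probes)}
    # 6 values 1..6 -> lowest decile = 1 value -> median 1.0
    assert array_background([ps], intens) == 1.0
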