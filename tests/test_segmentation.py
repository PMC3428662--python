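"""Distance-aware HMM: transitions, Viterbi, hard-EM training, call extraction."""

import itertools

import numpy as np
import pytest

import wavecnv as w
from wavecnv.errors import (
    InvalidDistanceError,
    InvalidInputError,
    InvalidObservationError,
)
from wavecnv.segmentation import _log_emissions


def make_track(values, positions=None, chrom="chr1", sample_id="s"):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = 1000 * (np.arange(len(values)) + 1)
    loci = [(f"ps{i}", chrom, int(p)) for i, p in enumerate(positions)]
    return w.RawCNTrack(sample_id=sample_id, loci=loci, values=values)


def viterbi_by_enumeration(track, params):
    """Independent oracle: score every one of the 5^n paths."""
    n = len(track.loci)
    pos = [p for _, _, p in track.loci]
    logem = _log_emissions(track.values, params)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.initial_dist)
        logA = [
            np.log(w.transition_matrix(pos[t] - pos[t - 1], params))
            for t in range(1, n)
        ]
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(5), repeat=n):
        lp = logpi[path[0]] + logem[0, path[0]]
        for t in range(1, n):
            lp += logA[t - 1][path[t - 1], path[t]] + logem[t, path[t]]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return best_lp, best_path


class TestTransitionMatrix:
    def test_tiny_distance_is_identity(self):
        params = w.HMMParameters()
        A = w.transition_matrix(1, params)
        assert np.abs(A - np.eye(5)).max() < 1e-4

    def test_large_distance_reaches_base(self):
        params = w.HMMParameters()
        A = w.transition_matrix(10 * params.distance_scale, params)
        assert np.abs(A - params.base_transition).max() < 1e-4

    @pytest.mark.parametrize("d", [1, 500, 3000, 100_000, 10**7])
    def test_convex_combination_oracle_and_row_sums(self, d):
        params = w.HMMParameters()
        f = 1.0 - np.exp(-d / params.distance_scale)
        expected = (1 - f) * np.eye(5) + f * params.base_transition
        A = w.transition_matrix(d, params)
        np.testing.assert_allclose(A, expected, rtol=1e-12)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(InvalidDistanceError):
            w.transition_matrix(0, w.HMMParameters())


class TestViterbi:
    def test_diploid_observations_give_diploid_path(self):
        track = make_track([2.0] * 30)
        res = w.viterbi(track, w.HMMParameters())
        assert (res.path == 2).all()

    def test_single_zero_locus_decodes_deletion(self):
        track = make_track([0.0])
        params = w.HMMParameters()
        res = w.viterbi(track, params)
        # manual argmax of initial_dist * emission at value 0
        scores = np.log(params.initial_dist) + _log_emissions(
            np.array([0.0]), params
        )[0]
        assert res.path[0] == int(np.argmax(scores)) == 0
        assert res.log_probability == pytest.approx(scores.max())

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        params = w.HMMParameters()
        for _ in range(30):
            n = int(rng.integers(1, 7))
            pos = np.sort(
                rng.choice(np.arange(1, 500_000), size=n, replace=False)
            )
            track = make_track(rng.uniform(-0.5, 4.5, n), positions=pos)
            res = w.viterbi(track, params)
            lp, path = viterbi_by_enumeration(track, params)
            assert res.log_probability == pytest.approx(lp, abs=1e-9)
            assert tuple(res.path) == path

    def test_empty_track_is_empty_result(self):
        track = w.RawCNTrack("s", [], np.empty(0))
        res = w.viterbi(track, w.HMMParameters())
        assert len(res.path) == 0

    def test_non_finite_observation_rejected(self):
        track = make_track([2.0, np.nan, 2.0])
        with pytest.raises(InvalidObservationError):
            w.viterbi(track, w.HMMParameters())

    def test_position_shift_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 4, 40)
        pos = np.sort(rng.choice(np.arange(1, 10**6), 40, replace=False))
        params = w.HMMParameters()
        r1 = w.viterbi(make_track(vals, pos), params)
        r2 = w.viterbi(make_track(vals, pos + 7_654_321), params)
        assert np.array_equal(r1.path, r2.path)
        assert r1.log_probability == pytest.approx(r2.log_probability)

    def test_beats_all_normal_path(self):
        rng = np.random.default_rng(2)
        params = w.HMMParameters()
        for _ in range(10):
            n = int(rng.integers(2, 50))
            track = make_track(rng.uniform(0, 4.5, n))
            res = w.viterbi(track, params)
            logem = _log_emissions(track.values, params)
            lp_normal = np.log(params.initial_dist[2]) + logem[0, 2]
            for t in range(1, n):
                pos = [p for _, _, p in track.loci]
                A = w.transition_matrix(pos[t] - pos[t - 1], params)
                lp_normal += np.log(A[2, 2]) + logem[t, 2]
            assert res.log_probability >= lp_normal - 1e-12


class TestViterbiTrain:
    def test_near_exact_track_converges_fast(self):
        rng = np.random.default_rng(3)
        states = np.array([2] * 20 + [1] * 8 + [2] * 20)
        vals = states + rng.normal(0, 0.01, states.size)
        params, res = w.viterbi_train(make_track(vals), w.HMMParameters())
        assert res.converged
        assert res.iterations <= 3
        assert np.array_equal(res.path, states)

    def test_zero_iterations_returns_input(self):
        params = w.HMMParameters()
        track = make_track([2.0, 2.0, 1.0])
        out_params, res = w.viterbi_train(track, params, max_iter=0)
        assert out_params is params
        assert np.array_equal(res.path, w.viterbi(track, params).path)

    def test_sd_never_exceeds_raw_deviation(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 4.5, 200)
        params, _ = w.viterbi_train(make_track(vals), w.HMMParameters())
        means = w.HMMParameters().emission_means
        nearest = means[np.argmin(np.abs(vals[:, None] - means[None, :]), axis=1)]
        raw_sd = np.sqrt(np.mean((vals - nearest) ** 2))
        assert params.emission_sd <= max(raw_sd, 0.05) + 1e-12

    def test_recovers_embedded_cnvs(self):
        """Two planted aberrations: >= 95% of loci decoded to true state."""
        rng = np.random.default_rng(5)
        states = np.array(
            [2] * 60 + [1] * 15 + [2] * 60 + [3] * 15 + [2] * 50
        )
        vals = states + rng.normal(0, 0.25, states.size)
        _, res = w.viterbi_train(make_track(vals), w.HMMParameters())
        assert (res.path == states).mean() >= 0.95


class TestExtractCalls:
    def test_run_of_five_is_called(self):
        path = np.array([2, 2, 1, 1, 1, 1, 1, 2])
        track = make_track([2, 2, 1, 1, 1, 1, 1, 2])
        res = w.SegmentationResult("s", path, -1.0)
        calls = w.extract_calls(res, track.loci, track.values)
        assert len(calls) == 1
        c = calls[0]
        assert (c.copy_state, c.n_probes) == (1, 5)
        assert c.start == track.loci[2][2] - 1
        assert c.end == track.loci[6][2]
        assert c.mean_raw_cn == pytest.approx(1.0)

    def test_short_run_filtered(self):
        path = np.array([2, 1, 1, 1, 1, 2])
        track = make_track(path.astype(float))
        res = w.SegmentationResult("s", path, -1.0)
        assert w.extract_calls(res, track.loci, track.values) == []

    def test_matches_run_scan_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            path = rng.choice(5, n, p=[0.05, 0.15, 0.55, 0.15, 0.1])
            track = make_track(path.astype(float))
            res = w.SegmentationResult("s", path, -1.0)
            calls = w.extract_calls(res, track.loci, min_probes=3)
            # explicit-loop oracle
            expected = []
            i = 0
            while i < n:
                j = i
                while j + 1 < n and path[j + 1] == path[i]:
                    j += 1
                if path[i] != 2 and j - i + 1 >= 3:
                    expected.append((int(path[i]), i, j))
                i = j + 1
            assert [
                (c.copy_state, c.start, c.end, c.n_probes) for c in calls
            ] == [
                (s, track.loci[i][2] - 1, track.loci[j][2], j - i + 1)
                for s, i, j in expected
            ]

    def test_calls_never_span_chromosomes(self):
        loci = [("a", "chr1", 1000), ("b", "chr1", 2000), ("c", "chr2", 1000),
                ("d", "chr2", 2000), ("e", "chr2", 3000)]
        path = np.array([1, 1, 1, 1, 1])
        res = w.SegmentationResult("s", path, -1.0)
        calls = w.extract_calls(res, loci, min_probes=2)
        assert [(c.chrom, c.n_probes) for c in calls] == [
            ("chr1", 2), ("chr2", 3)
        ]


class TestHMMParametersSerialization:
    def test_json_round_trip(self, tmp_path):
        params = w.HMMParameters(emission_sd=0.27, distance_scale=55_000)
        path = tmp_path / "hmm.json"
        params.to_json(path)
        back = w.HMMParameters.from_json(path)
        np.testing.assert_allclose(back.base_transition, params.base_transition)
        assert back.emission_sd == params.emission_sd
        assert back.distance_scale == params.distance_scale

    def test_invalid_rows_rejected(self):
        bad = np.full((5, 5), 0.2)
        bad[0, 0] = 0.5
        with pytest.raises(InvalidInputError):
            w.HMMParameters(base_transition=bad)
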