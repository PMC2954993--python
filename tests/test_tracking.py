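"""Fingerprints, combinatorics, trackers, stability, evaluation."""

import numpy as np
import pytest

import spectrack as st
from spectrack import tracking as trk
from spectrack.tracking import Detection, Track


def _fp(*intensities):
    return trk.compute_fingerprint(np.array(intensities, dtype=float))


class TestFingerprint:
    def test_fractions_and_rank_order(self):
        fp = _fp(30.0, 60.0, 10.0)
        assert np.allclose(fp.fractions, (0.3, 0.6, 0.1))
        assert fp.rank_order == (1, 0, 2)  # G > R > B ordering by fraction
        assert not fp.degenerate

    def test_support_excludes_missing_fluorophore(self):
        # a cell with GFP and RFP signal and no YFP
        fp = _fp(80.0, 0.0, 40.0)
        assert fp.support == {0, 2}

    def test_uniform_intensities_flagged_degenerate(self):
        fp = _fp(10.0, 10.0, 10.0)
        assert fp.degenerate
        assert fp.rank_order == (0, 1, 2)  # ties broken by channel order

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            _fp(0.0, 0.0, 0.0)

    def test_invariant_under_global_scaling(self):
        a, b = _fp(30.0, 60.0, 10.0), _fp(90.0, 180.0, 30.0)
        assert trk.fingerprint_distance(a, b)[0] == 0.0


class TestFingerprintDistance:
    def test_identical_fingerprints_distance_zero(self):
        d, rank_ok = trk.fingerprint_distance(_fp(1, 2, 3), _fp(1, 2, 3))
        assert d == 0.0 and rank_ok

    def test_disjoint_supports_distance_two(self):
        d, _ = trk.fingerprint_distance(_fp(1, 0, 0), _fp(0, 1, 0))
        assert d == 2.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = _fp(*rng.uniform(0.1, 10, size=3))
            b = _fp(*rng.uniform(0.1, 10, size=3))
            assert trk.fingerprint_distance(a, b)[0] == \
                   trk.fingerprint_distance(b, a)[0]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            trk.fingerprint_distance(_fp(1, 2), _fp(1, 2, 3))


class TestCombinatorics:
    @pytest.mark.parametrize("k,expected", [(1, 1), (4, 24), (5, 120)])
    def test_colocated_cells_admit_k_factorial_outcomes(self, k, expected):
        assert st.ambiguity_count(k) == expected

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 3), (3, 7)])
    def test_nonempty_label_subsets(self, n, expected):
        assert st.count_color_combinations(n) == expected

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            st.ambiguity_count(0)
        with pytest.raises(ValueError):
            st.count_color_combinations(0)


def _stationary_detections(n_frames=5):
    return [
        [Detection(10.0, 10.0, _fp(9, 1, 0), truth_id=0),
         Detection(60.0, 60.0, _fp(1, 9, 0), truth_id=1)]
        for _ in range(n_frames)
    ]


class TestNearestNeighborTrack:
    def test_two_separated_cells_two_clean_tracks(self):
        tracks, report = trk.nearest_neighbor_track(_stationary_detections())
        assert len(tracks) == 2
        assert trk.evaluate_tracking(tracks).identity_switches == 0
        assert report.conflict_events == 0

    def test_disappearing_cell_terminates_track(self):
        dets = _stationary_detections(6)
        for t in range(3, 6):
            dets[t] = [dets[t][0]]  # second cell vanishes mid-movie
        tracks, _ = trk.nearest_neighbor_track(dets, gate=30.0)
        by_len = sorted(tracks, key=lambda tr: len(tr.frames))
        assert len(by_len[0].frames) == 3  # terminated, no jump beyond gate
        assert len(by_len[-1].frames) == 6

    def test_symmetric_swap_is_a_coin_flip_over_seeds(self):
        """Blind tracking through a symmetric swap is wrong about half the
        time once detection jitter decides the tie."""
        wrong = 0
        n = 60
        for s in range(n):
            movie = st.make_crossing_scenario(seed=s, render=False)
            dets = trk.detections_from_truth(movie, position_noise=0.3,
                                             intensity_noise=0.1, seed=s + 1)
            tracks, _ = trk.nearest_neighbor_track(dets)
            wrong += trk.evaluate_tracking(tracks).identity_switches > 0
        assert 0.25 <= wrong / n <= 0.75

    def test_needs_at_least_two_frames(self):
        with pytest.raises(ValueError):
            trk.nearest_neighbor_track([_stationary_detections(1)[0]])


class TestSpectralTrack:
    def test_noiseless_crossing_zero_switches(self):
        movie = st.make_crossing_scenario(seed=0, render=False)
        dets = trk.detections_from_truth(movie, position_noise=0.0, seed=0)
        tracks, report = trk.spectral_track(dets)
        assert trk.evaluate_tracking(tracks).identity_switches == 0
        assert report.conflict_events == 1

    def test_identical_fingerprints_flag_ambiguous(self):
        movie = st.make_crossing_scenario(seed=1, render=False)
        for cell in movie.truth:
            cell.expression = np.array([100.0, 50.0, 0.0])
        dets = trk.detections_from_truth(movie, position_noise=0.2, seed=1)
        _, report = trk.spectral_track(dets)
        assert report.ambiguous >= 1

    def test_weight_zero_identical_to_nearest_neighbor(self):
        movie = st.make_crossing_scenario(seed=2, render=False)
        dets = trk.detections_from_truth(movie, position_noise=0.3,
                                         intensity_noise=0.1, seed=2)
        a, _ = trk.spectral_track(dets, weight=0.0)
        b, _ = trk.nearest_neighbor_track(dets)
        assert [tr.truth_ids for tr in a] == [tr.truth_ids for tr in b]

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            trk.spectral_track(_stationary_detections(), weight=-1.0)

    def test_beats_blind_tracking_on_crossings(self):
        """Paired seeds: spectral switch rate is far below the blind rate."""
        n = 100
        wrong_s = wrong_n = 0
        for s in range(n):
            movie = st.make_crossing_scenario(seed=s, render=False)
            dets = trk.detections_from_truth(movie, position_noise=0.3,
                                             intensity_noise=0.1, seed=s + 7)
            ts, _ = trk.spectral_track(dets)
            tn, _ = trk.nearest_neighbor_track(dets)
            wrong_s += trk.evaluate_tracking(ts).identity_switches > 0
            wrong_n += trk.evaluate_tracking(tn).identity_switches > 0
        p_n = wrong_n / n
        se = np.sqrt(max(p_n * (1 - p_n), 1e-4) / n)
        assert wrong_s / n <= 0.02
        assert p_n - wrong_s / n > 3 * se

    def test_division_daughters_follow_parent_lineage(self):
        movie = st.make_division_scenario(render=False)
        dets = trk.detections_from_truth(movie, position_noise=0.1, seed=0)
        tracks, _ = trk.spectral_track(dets)
        parent_map = {c.id: c.parent for c in movie.truth}
        assert trk.evaluate_tracking(tracks, parent_map).identity_switches == 0


class TestFingerprintStability:
    def _track_from_series(self, fps):
        tr = Track(id=0)
        for t, fp in enumerate(fps):
            tr.append(t, Detection(0.0, 0.0, fp))
        return tr

    def test_constant_expression_perfectly_stable(self):
        tr = self._track_from_series([_fp(60, 30, 10)] * 10)
        assert trk.fingerprint_stability(tr)["stability"] == 1.0

    def test_equal_bleaching_leaves_stability_one(self):
        fps = [_fp(60 * np.exp(-0.1 * t), 30 * np.exp(-0.1 * t),
                   10 * np.exp(-0.1 * t)) for t in range(10)]
        assert trk.fingerprint_stability(self._track_from_series(fps))["stability"] == 1.0

    def test_hierarchical_cells_stable_under_10pct_noise(self):
        """Modal rank order holds in >= 95% of frames for >= 95% of cells."""
        ok = 0
        n = 200
        for s in range(n):
            movie = st.make_random_walk_movie(
                n_cells=1, n_frames=60, seed=s,
                expression_mode="hierarchical", render=False)
            dets = trk.detections_from_truth(movie, position_noise=0.3,
                                             intensity_noise=0.1, seed=s + 999)
            tracks, _ = trk.nearest_neighbor_track(dets)
            ok += trk.fingerprint_stability(tracks[0])["stability"] >= 0.95
        assert ok / n >= 0.95

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            trk.fingerprint_stability(self._track_from_series([_fp(1, 2, 3)]))


def _track_with_labels(labels, start=0):
    tr = Track(id=0)
    for t, lab in enumerate(labels):
        tr.append(start + t, Detection(0.0, 0.0, None, truth_id=lab))
    return tr


class TestEvaluateTracking:
    def test_faithful_tracks_zero_switches(self):
        tracks = [_track_with_labels([0] * 5), _track_with_labels([1] * 5)]
        assert trk.evaluate_tracking(tracks).identity_switches == 0

    def test_swapped_labels_after_frame_t_two_switches(self):
        tracks = [_track_with_labels([0, 0, 1, 1]),
                  _track_with_labels([1, 1, 0, 0])]
        assert trk.evaluate_tracking(tracks).identity_switches == 2

    def test_daughter_transition_is_not_a_switch(self):
        tracks = [_track_with_labels([0, 0, 1, 1])]
        assert trk.evaluate_tracking(tracks, {1: 0}).identity_switches == 0

    def test_random_permutations_match_brute_force(self, rng):
        """3 cells, 10 frames, labels permuted per frame: switch count
        equals a direct recount of adjacent label changes."""
        for _ in range(20):
            label_matrix = np.array([rng.permutation(3) for _ in range(10)]).T
            tracks = [_track_with_labels(list(row)) for row in label_matrix]
            expected = sum(
                int(row[t] != row[t + 1])
                for row in label_matrix for t in range(9)
            )
            assert trk.evaluate_tracking(tracks).identity_switches == expected

    def test_missing_truth_labels_rejected(self):
        tr = Track(id=0)
        tr.append(0, Detection(0.0, 0.0, None))
        tr.append(1, Detection(0.0, 0.0, None))
        with pytest.raises(ValueError):
            trk.evaluate_tracking([tr])
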