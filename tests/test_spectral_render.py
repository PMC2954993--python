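"""Synthetic-data generator: channelization, spectra, rendering, scenarios."""

import numpy as np
import pytest

import spectrack as st
from spectrack.spectral_render import ChannelLayout, NoiseParams
from spectrack import tracking as trk


class TestLambdaChannels:
    @pytest.mark.parametrize("lo,hi,step,expected", [
        (571.0, 657.0, 10.7, 8),    # single-FP nuclear label configuration
        (494.0, 623.0, 10.7, 12),   # 3-FP configuration
        (571.0, 581.7, 10.7, 1),    # exactly one step
    ])
    def test_channel_count(self, lo, hi, step, expected):
        assert st.lambda_channels(lo, hi, step) == expected

    def test_range_smaller_than_step_rejected(self):
        with pytest.raises(ValueError):
            st.lambda_channels(571.0, 575.0, 10.7)


class TestReferenceSpectra:
    def test_columns_sum_to_one(self, gyr_spectra):
        assert np.allclose(gyr_spectra.matrix.sum(axis=0), 1.0)

    def test_single_fluorophore_single_unit_column(self):
        spectra = st.make_reference_spectra([st.Fluorophore("GFP", 507.0)])
        assert spectra.matrix.shape[1] == 1
        assert np.isclose(spectra.matrix.sum(), 1.0)

    def test_peak_centered_in_channel_gives_argmax_there(self):
        layout = ChannelLayout(lambda_min=494.0, lambda_max=623.0, step=10.7)
        centers = layout.channel_centers()
        k = 5
        spectra = st.make_reference_spectra(
            [st.Fluorophore("X", float(centers[k]))], layout)
        assert int(np.argmax(spectra.matrix[:, 0])) == k

    def test_spectral_proximity_raises_cosine_similarity(self):
        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        far = st.make_reference_spectra(
            [st.Fluorophore("A", 500.0), st.Fluorophore("B", 600.0)])
        near = st.make_reference_spectra(
            [st.Fluorophore("A", 500.0), st.Fluorophore("B", 520.0)])
        assert cos(far.matrix[:, 0], far.matrix[:, 1]) < \
               cos(near.matrix[:, 0], near.matrix[:, 1])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            st.make_reference_spectra(
                [st.Fluorophore("A", 500.0), st.Fluorophore("A", 510.0)])

    def test_autofluorescence_column_appended(self, gyr_spectra):
        spectra = st.make_reference_spectra(
            st.DEFAULT_FLUOROPHORES[1:4], include_autofluorescence=True)
        assert spectra.labels[-1] == "autofluorescence"
        assert spectra.matrix.shape[1] == gyr_spectra.matrix.shape[1] + 1


class TestRenderFrame:
    def test_no_cells_no_noise_is_uniform_background(self, gyr_spectra):
        frame = st.render_frame([], [], gyr_spectra, field_size=(20, 20),
                                pixel_size=1.0, noise=NoiseParams(background=3.0))
        assert np.allclose(frame, 3.0)

    def test_single_fluorophore_pixels_proportional_to_column(self, gyr_spectra):
        frame = st.render_frame([[10.0, 10.0]], [[100.0, 0.0, 0.0]], gyr_spectra,
                                field_size=(20, 20), pixel_size=1.0)
        col = gyr_spectra.matrix[:, 0]
        mask = frame.sum(axis=0) > 1e-3
        vecs = frame[:, mask]
        vecs = vecs / vecs.sum(axis=0, keepdims=True)
        assert np.allclose(vecs, col[:, None], atol=1e-9)

    def test_signal_linear_in_expression(self, gyr_spectra):
        f1 = st.render_frame([[10.0, 10.0]], [[50.0, 20.0, 0.0]], gyr_spectra,
                             field_size=(20, 20), pixel_size=1.0)
        f2 = st.render_frame([[10.0, 10.0]], [[100.0, 40.0, 0.0]], gyr_spectra,
                             field_size=(20, 20), pixel_size=1.0)
        assert np.allclose(f2, 2.0 * f1, rtol=1e-9)

    def test_superposition_of_cells(self, gyr_spectra):
        fa = st.render_frame([[5.0, 5.0]], [[40.0, 0, 0]], gyr_spectra,
                             field_size=(20, 20), pixel_size=1.0)
        fb = st.render_frame([[15.0, 15.0]], [[0, 0, 70.0]], gyr_spectra,
                             field_size=(20, 20), pixel_size=1.0)
        fab = st.render_frame([[5.0, 5.0], [15.0, 15.0]],
                              [[40.0, 0, 0], [0, 0, 70.0]], gyr_spectra,
                              field_size=(20, 20), pixel_size=1.0)
        assert np.allclose(fab, fa + fb, rtol=1e-9)

    def test_negative_expression_rejected(self, gyr_spectra):
        with pytest.raises(ValueError):
            st.render_frame([[5.0, 5.0]], [[-1.0, 0, 0]], gyr_spectra,
                            field_size=(10, 10), pixel_size=1.0)

    def test_channel_mode_equals_grouped_lambda_bins(self):
        """Bandpass windows tiling the lambda range sum the lambda bins."""
        flus = st.DEFAULT_FLUOROPHORES[1:4]
        lam = ChannelLayout(lambda_min=494.0, lambda_max=623.0, step=10.7)
        edges = lam.band_edges()
        groups = [(0, 4), (4, 8), (8, 12)]
        bands = tuple((float(edges[a, 0]), float(edges[b - 1, 1])) for a, b in groups)
        chan = ChannelLayout(mode="CHANNEL", bands=bands)
        s_lam = st.make_reference_spectra(flus, lam)
        s_chan = st.make_reference_spectra(flus, chan)
        pos, expr = [[10.0, 10.0]], [[30.0, 60.0, 10.0]]
        f_lam = st.render_frame(pos, expr, s_lam, field_size=(20, 20), pixel_size=1.0)
        f_chan = st.render_frame(pos, expr, s_chan, field_size=(20, 20), pixel_size=1.0)
        summed = np.stack([f_lam[a:b].sum(axis=0) for a, b in groups])
        assert np.allclose(f_chan, summed, rtol=1e-6, atol=1e-9)


class TestCrossingScenario:
    def test_two_cell_crossing_has_one_conflict(self):
        movie = st.make_crossing_scenario(n_cells=2, seed=0, render=False)
        dets = trk.detections_from_truth(movie, position_noise=0.0, seed=0)
        _, report = trk.spectral_track(dets)
        assert report.conflict_events == 1

    def test_four_cell_conflict_admits_24_reassignments(self):
        movie = st.make_crossing_scenario(n_cells=4, fingerprint_separation=0.5,
                                          seed=1, render=False)
        dets = trk.detections_from_truth(movie, position_noise=0.0, seed=0)
        _, report = trk.spectral_track(dets)
        ks = [len(ev.track_ids) for ev in report.conflicts]
        assert max(ks) == 4
        assert st.ambiguity_count(max(ks)) == 24

    def test_paths_separated_at_movie_ends(self):
        movie = st.make_crossing_scenario(n_cells=3, fingerprint_separation=0.5,
                                          seed=2, render=False)
        diam = movie.truth[0].nuclear_diameter
        for t in (0, movie.n_frames - 1):
            pos = np.array([c.path[t] for c in movie.truth])
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    assert np.linalg.norm(pos[i] - pos[j]) >= 2 * diam

    def test_fingerprint_separation_honored(self):
        movie = st.make_crossing_scenario(n_cells=3, fingerprint_separation=0.6,
                                          seed=3, render=False)
        fps = [c.expression / c.expression.sum() for c in movie.truth]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.abs(fps[i] - fps[j]).sum() >= 0.6

    def test_infeasible_separation_rejected(self):
        with pytest.raises(ValueError):
            st.make_crossing_scenario(n_cells=7, fingerprint_separation=1.9)

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError):
            st.make_crossing_scenario(n_cells=1)


class TestDivisionScenario:
    def test_noiseless_daughters_inherit_expression(self):
        movie = st.make_division_scenario(render=False)
        parent, d1, d2 = movie.truth
        assert np.array_equal(d1.expression, parent.expression)
        assert np.array_equal(d2.expression, parent.expression)

    def test_lineage_records_parent_on_both_daughters(self):
        movie = st.make_division_scenario(render=False)
        assert movie.truth[1].parent == movie.truth[0].id
        assert movie.truth[2].parent == movie.truth[0].id

    def test_split_frame_outside_movie_rejected(self):
        with pytest.raises(ValueError):
            st.make_division_scenario(split_frame=40, n_frames=31)

    def test_rank_order_survives_10pct_partition_noise(self):
        """Daughter fingerprints keep the parent's intensity hierarchy in
        >= 95% of seeded divisions under 10% multiplicative noise."""
        parent_fp = trk.compute_fingerprint(np.array([200.0, 100.0, 0.0]))
        ok = 0
        n_runs = 1000
        for s in range(n_runs):
            movie = st.make_division_scenario(
                parent_expression=(200.0, 100.0, 0.0), daughter_noise=0.10,
                seed=s, render=False)
            ranks = [trk.compute_fingerprint(c.expression).rank_order
                     for c in movie.truth[1:]]
            ok += all(r == parent_fp.rank_order for r in ranks)
        assert ok / n_runs >= 0.95


class TestReproducibility:
    def test_movie_bit_exact_for_fixed_seed(self):
        a = st.make_crossing_scenario(seed=5, n_frames=7, field_size=(40, 40),
                                      noise=NoiseParams(poisson=True, read_sigma=1.0,
                                                        background=2.0))
        b = st.make_crossing_scenario(seed=5, n_frames=7, field_size=(40, 40),
                                      noise=NoiseParams(poisson=True, read_sigma=1.0,
                                                        background=2.0))
        assert np.array_equal(a.frames, b.frames)
        assert all(np.array_equal(x.path, y.path) for x, y in zip(a.truth, b.truth))

    def test_equal_photobleaching_preserves_fingerprints(self, gyr_spectra):
        cells = [st.SyntheticCell(0, np.tile([20.0, 20.0], (5, 1)),
                                  np.array([60.0, 30.0, 10.0]))]
        movie = st.render_movie(cells, gyr_spectra, 5, field_size=(40, 40),
                                pixel_size=1.0, bleach_rates=np.array([0.1] * 3))
        # channel composition at the cell center is constant over time
        center = movie.frames[:, :, 20, 20]
        comp = center / center.sum(axis=1, keepdims=True)
        assert np.allclose(comp, comp[0], atol=1e-9)
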