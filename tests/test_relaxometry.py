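"""EPG simulation, dictionary construction, T2/PD and fat-fraction fitting."""

import numpy as np
import pytest

from imatseg.acquisition import EchoSeries, Protocol
from imatseg import labels as L
from imatseg.relaxometry import (build_dictionary, epg_mese_curve, fit_t2_pd,
                                 fit_two_component, label_tissue_gt)
from oracles import isochromat_mese, two_component_grid_search


class TestEpgCurve:
    def test_perfect_refocusing_is_monoexponential(self, protocol):
        curve = epg_mese_curve(50.0, 1400.0, 1.0, protocol)
        expected = np.exp(-protocol.echo_times / 50.0)
        assert np.allclose(curve, expected, rtol=1e-6)

    def test_no_refocusing_gives_no_echoes(self, protocol):
        assert epg_mese_curve(50.0, 1400.0, 0.0, protocol).max() == 0.0

    def test_matches_isochromat_simulation(self, protocol):
        # spot check away from the trivial 180-degree limit
        epg = epg_mese_curve(40.0, 1400.0, 0.8, protocol)
        oracle = isochromat_mese(40.0, 1400.0, 0.8, protocol, n_iso=2000)
        assert np.abs(epg - oracle).max() / oracle.max() < 1e-3

    def test_curves_decrease_at_ideal_refocusing(self, protocol):
        curve = epg_mese_curve(80.0, 1400.0, 1.0, protocol)
        assert (np.diff(curve) < 0).all()

    def test_rejects_nonpositive_relaxation_times(self, protocol):
        with pytest.raises(ValueError):
            epg_mese_curve(-5.0, 1400.0, 1.0, protocol)
        with pytest.raises(ValueError):
            epg_mese_curve(50.0, 0.0, 1.0, protocol)


class TestDictionary:
    def test_default_grid_dimensions(self, dictionary):
        assert dictionary.curves.shape == (146, 31, 17)
        assert np.isclose(dictionary.t2_grid[1] - dictionary.t2_grid[0], 2.0)
        assert np.isclose(dictionary.b1_grid[1] - dictionary.b1_grid[0], 0.02)

    def test_entries_are_unit_norm(self, dictionary):
        norms = np.linalg.norm(dictionary.curves, axis=-1)
        assert np.abs(norms - 1.0).max() < 1e-12

    def test_rebuild_hits_cache_byte_identical(self, protocol, tmp_path):
        from imatseg import relaxometry

        grids = dict(t2_grid=np.array([30.0, 60.0, 90.0]),
                     b1_grid=np.array([0.9, 1.0, 1.1]))
        d1 = build_dictionary(protocol, cache_dir=tmp_path, **grids)
        files = list(tmp_path.glob("dict_*.npz"))
        assert files
        relaxometry._MEMO.clear()          # force the disk-cache path
        d2 = build_dictionary(protocol, cache_dir=tmp_path, **grids)
        assert np.array_equal(d1.curves, d2.curves)
        assert np.array_equal(d1.raw_first_echo, d2.raw_first_echo)

    def test_rejects_degenerate_grids(self, protocol):
        with pytest.raises(ValueError):
            build_dictionary(protocol, t2_grid=np.array([50.0, 40.0]))
        with pytest.raises(ValueError):
            build_dictionary(protocol, b1_grid=np.array([]))


class TestFitT2Pd:
    def test_identity_on_dictionary_member(self, protocol, dictionary):
        it2 = int(dictionary.nearest_t2_index(40.0))
        ib1 = int(dictionary.nearest_b1_index(1.0))
        signal = 100.0 * dictionary.unnormalized_curves[it2, ib1]
        series = EchoSeries(signal[None, None, :], protocol)
        maps = fit_t2_pd(series, dictionary)
        assert maps.t2[0, 0] == 40.0
        assert maps.b1_plus[0, 0] == 1.0
        assert maps.fit_residual[0, 0] <= 1e-10

    def test_all_zero_pixel_is_invalid_not_fatal(self, protocol, dictionary):
        data = np.zeros((2, 2, protocol.n_echoes))
        data[0, 0] = 50.0 * dictionary.unnormalized_curves[30, 15]
        maps = fit_t2_pd(EchoSeries(data, protocol), dictionary)
        assert maps.valid_mask[0, 0]
        assert not maps.valid_mask[1, 1]
        assert maps.t2[1, 1] == 0.0

    def test_median_t2_within_one_grid_step_under_noise(self, protocol,
                                                        dictionary):
        t2_true, b1 = 45.0, 1.0   # a grid member
        it2 = int(dictionary.nearest_t2_index(t2_true))
        ib1 = int(dictionary.nearest_b1_index(b1))
        curve = dictionary.unnormalized_curves[it2, ib1]
        n = 500
        clean = 100.0 * np.tile(curve, (n, 1))
        sigma = clean[:, 0].mean() / 50.0
        rng = np.random.default_rng(21)
        noisy = np.sqrt(
            (clean + rng.normal(0, sigma, clean.shape)) ** 2
            + rng.normal(0, sigma, clean.shape) ** 2)
        series = EchoSeries(noisy.reshape(n, 1, -1), protocol)
        maps = fit_t2_pd(series, dictionary)
        assert abs(np.median(maps.t2[maps.valid_mask]) - t2_true) <= 2.0

    def test_pd_backprojects_first_echo(self, protocol, dictionary):
        it2 = int(dictionary.nearest_t2_index(40.0))
        ib1 = int(dictionary.nearest_b1_index(1.0))
        signal = 7.5 * dictionary.unnormalized_curves[it2, ib1]
        maps = fit_t2_pd(EchoSeries(signal[None, None, :], protocol),
                         dictionary)
        expected = signal[0] * np.exp(protocol.echo_spacing / 40.0)
        assert maps.pd[0, 0] == pytest.approx(expected)

    def test_rejects_echo_count_mismatch(self, dictionary):
        short = Protocol(n_echoes=5)
        series = EchoSeries(np.ones((2, 2, 5)), short)
        with pytest.raises(ValueError):
            fit_t2_pd(series, dictionary)


class TestFitTwoComponent:
    def _pixel_series(self, dictionary, protocol, t2w, ff, b1=1.0,
                      amp=100.0, t2f=150.0):
        cu = dictionary.unnormalized_curves
        jb = int(dictionary.nearest_b1_index(b1))
        w = cu[int(dictionary.nearest_t2_index(t2w)), jb]
        f = cu[int(dictionary.nearest_t2_index(t2f)), jb]
        sig = amp * ((1 - ff) * w + ff * f)
        return EchoSeries(sig[None, None, :], protocol)

    def test_pure_water_pixel(self, protocol, dictionary):
        series = self._pixel_series(dictionary, protocol, 40.0, 0.0)
        ff, _ = fit_two_component(series, dictionary, np.ones((1, 1), bool))
        assert ff[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_pure_fat_pixel(self, protocol, dictionary):
        series = self._pixel_series(dictionary, protocol, 40.0, 1.0)
        ff, _ = fit_two_component(series, dictionary, np.ones((1, 1), bool))
        assert ff[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_mixture_matches_grid_search_oracle(self, protocol, dictionary):
        series = self._pixel_series(dictionary, protocol, 40.0, 0.7)
        ff, t2w = fit_two_component(series, dictionary,
                                    np.ones((1, 1), bool))
        oracle = two_component_grid_search(series.data[0, 0], dictionary, 1.0)
        assert abs(ff[0, 0] - 0.7) <= 0.05
        assert abs(ff[0, 0] - oracle) <= 0.05

    def test_pixels_outside_mask_untouched(self, protocol, dictionary):
        series = self._pixel_series(dictionary, protocol, 40.0, 0.5)
        data = np.tile(series.data, (2, 2, 1))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        ff, _ = fit_two_component(EchoSeries(data, protocol), dictionary, mask)
        assert ff[0, 1] == 0.0 and ff[1, 1] == 0.0
        assert ff[0, 0] > 0.3

    def test_rejects_fat_anchor_outside_grid(self, protocol, dictionary):
        series = self._pixel_series(dictionary, protocol, 40.0, 0.5)
        with pytest.raises(ValueError):
            fit_two_component(series, dictionary, np.ones((1, 1), bool),
                              t2_fat_anchor=500.0)


class TestPhantomRecovery:
    """Noiseless phantom: fitted maps reproduce the ground truth."""

    def test_noiseless_t2_equals_nearest_grid_truth(self, standard_phantom,
                                                    noiseless_series,
                                                    dictionary):
        truth = standard_phantom
        pure = truth.muscle_region_mask & (truth.fat_fraction == 0.0)
        if not pure.any():
            pure = truth.muscle_region_mask & (truth.fat_fraction < 0.01)
        maps = fit_t2_pd(noiseless_series, dictionary,
                         truth.muscle_region_mask)
        t2_expected = dictionary.t2_grid[
            dictionary.nearest_t2_index(truth.t2_water)]
        close = np.abs(maps.t2[pure] - t2_expected[pure]) <= 2.0
        assert close.mean() >= 0.95

    def test_fat_fraction_recovery_and_gt_labels(self, standard_phantom,
                                                 noiseless_series,
                                                 dictionary):
        truth = standard_phantom
        mus = truth.muscle_region_mask
        ff, _ = fit_two_component(noiseless_series, dictionary, mus)
        err = np.abs(ff - truth.fat_fraction)[mus]
        assert (err <= 0.05).mean() >= 0.95
        lab = label_tissue_gt(ff, mus)
        for code, pred in ((L.VIABLE, lab.viable_mask),
                           (L.IMAT, lab.imat_mask)):
            ref = truth.tissue_mask == code
            dsc = 2 * (ref & pred).sum() / (ref.sum() + pred.sum())
            assert dsc >= 0.98


class TestLabelTissueGt:
    def test_threshold_is_strict(self):
        ff = np.array([[0.51, 0.50], [0.10, 0.90]])
        mask = np.ones((2, 2), bool)
        lab = label_tissue_gt(ff, mask)
        assert lab.labels[0, 0] == L.IMAT      # 0.51 > 0.5
        assert lab.labels[0, 1] == L.VIABLE    # exactly 0.5 stays viable
        assert lab.labels[1, 0] == L.VIABLE
        assert lab.labels[1, 1] == L.IMAT

    def test_outside_mask_is_background(self):
        ff = np.full((3, 3), 0.9)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        lab = label_tissue_gt(ff, mask)
        assert lab.labels[1, 1] == L.IMAT
        assert (lab.labels[~mask] == L.BACKGROUND).all()

    def test_empty_mask_gives_all_background(self):
        lab = label_tissue_gt(np.zeros((2, 2)), np.zeros((2, 2), bool))
        assert (lab.labels == L.BACKGROUND).all()
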