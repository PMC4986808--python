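"""Band areas, ratio features, PCA screen and the diagnostic model."""

import dataclasses

import numpy as np
import pytest

from ramanmsi import classifier as cl
from ramanmsi import readout as ro
from ramanmsi.acquisition import AcquisitionConfig, simulate_class_spectra


def spectrum_on_grid(y, lo=600.0, hi=1800.0):
    nu = np.arange(lo, hi + 0.5)
    return ro.Spectrum(wavenumber=nu, intensity=np.asarray(y, float))


def gaussian(nu, center, sigma, amp=1.0):
    return amp * np.exp(-0.5 * ((nu - center) / sigma) ** 2)


class TestBandAreas:
    def test_straight_line_spectrum_all_zero(self):
        nu = np.arange(600.0, 1801.0)
        for slope, icpt in [(0.0, 5.0), (0.03, -2.0), (-0.7, 100.0)]:
            s = spectrum_on_grid(slope * nu + icpt)
            areas = cl.band_areas(s).areas
            assert all(abs(a) < 1e-9 for a in areas.values())

    def test_gaussian_band_matches_trapezoid_oracle(self):
        nu = np.arange(600.0, 1801.0)
        y = gaussian(nu, 1001.0, 5.0)
        s = spectrum_on_grid(y)
        areas = cl.band_areas(s).areas
        # independent oracle: baseline through 3-sample edge means, trapezoid
        lo, hi = cl.BAND_WINDOWS_CM1["A4"]
        m = (nu >= lo) & (nu <= hi)
        wn, wy = nu[m], y[m]
        x0, y0 = wn[:3].mean(), wy[:3].mean()
        x1, y1 = wn[-3:].mean(), wy[-3:].mean()
        resid = wy - (y0 + (y1 - y0) / (x1 - x0) * (wn - x0))
        assert areas["A4"] == pytest.approx(np.trapezoid(resid, wn), rel=1e-12)
        for other in ("A1", "A5", "A6", "A7"):
            assert abs(areas[other]) < 1e-6

    def test_linearity_in_scaling(self):
        nu = np.arange(600.0, 1801.0)
        y = gaussian(nu, 860.0, 8.0) + gaussian(nu, 1290.0, 9.0)
        a1 = cl.band_areas(spectrum_on_grid(y)).areas
        a3 = cl.band_areas(spectrum_on_grid(3.0 * y)).areas
        for k in a1:
            assert a3[k] == pytest.approx(3.0 * a1[k], abs=1e-9)

    def test_window_not_covered_names_the_window(self):
        s = spectrum_on_grid(np.ones(401), lo=900.0, hi=1300.0)
        with pytest.raises(ValueError, match="772"):
            cl.band_areas(s)


class TestFeatureRatios:
    def test_equal_areas_give_unit_ratios(self):
        f = cl.BandFeatureSet(areas={k: 2.5 for k in cl.BAND_WINDOWS_CM1})
        assert np.allclose(cl.feature_ratios(f), 1.0)

    def test_scale_invariance_of_spectrum_features(self):
        nu = np.arange(600.0, 1801.0)
        y = (gaussian(nu, 788, 5) + gaussian(nu, 1004, 4)
             + gaussian(nu, 1098, 5) + gaussian(nu, 1250, 7)
             + gaussian(nu, 1300, 6))
        f1 = cl.spectrum_features(spectrum_on_grid(y))
        f2 = cl.spectrum_features(spectrum_on_grid(7.3 * y))
        # additive straight line also leaves ratios unchanged
        f3 = cl.spectrum_features(spectrum_on_grid(7.3 * y + 0.01 * nu - 3))
        assert np.allclose(f1, f2, rtol=1e-9)
        assert np.allclose(f1, f3, rtol=1e-6)

    def test_ratio_order_matches_definition(self):
        areas = {"A1": 2.0, "A2": 3.0, "A3": 4.0, "A4": 2.0, "A5": 5.0,
                 "A6": 6.0, "A7": 3.0}
        r = cl.feature_ratios(cl.BandFeatureSet(areas=areas))
        assert np.allclose(r, [1.0, 1.5, 2.0, 2.5, 2.0])

    def test_zero_denominator_flags_unclassifiable(self):
        areas = {k: 1.0 for k in cl.BAND_WINDOWS_CM1}
        areas["A4"] = 0.0
        with pytest.raises(cl.UnclassifiableSpectrum):
            cl.feature_ratios(cl.BandFeatureSet(areas=areas))


class TestPcaScreen:
    def _normalized(self, spectra):
        out = []
        for s in spectra:
            c = ro.snv_normalize(ro.crop_range(s, *ro.CLASSIFY_RANGE_CM1))
            out.append(c.intensity)
        return np.array(out), ro.crop_range(
            spectra[0], *ro.CLASSIFY_RANGE_CM1).wavenumber

    def test_homogeneous_set_nothing_removed(self, library, cfg):
        x, axis = self._normalized(
            simulate_class_spectra("dermis", 40, library, cfg, seed=0))
        labels = cl.pca_screen(x, library, axis=axis)
        assert np.all(labels == "keep")

    def test_spiked_fat_detected(self, library, cfg):
        dermis = simulate_class_spectra("dermis", 57, library, cfg, seed=1)
        fat = simulate_class_spectra("fat", 3, library, cfg, seed=2)
        x, axis = self._normalized(dermis + fat)
        labels = cl.pca_screen(x, library, axis=axis)
        assert np.mean(labels[-3:] == "fat") >= 0.9
        assert np.mean(labels[:57] == "keep") >= 0.95

    def test_dyed_spectra_detected(self, library, cfg):
        dermis = simulate_class_spectra("dermis", 56, library, cfg, seed=3)
        dyed = simulate_class_spectra("BCC", 4, library, cfg, seed=4,
                                      dyed=True)
        x, axis = self._normalized(dermis + dyed)
        labels = cl.pca_screen(x, library, axis=axis)
        assert np.mean(labels[-4:] == "dye") >= 0.75

    def test_deterministic_labels(self, library, cfg):
        spectra = (simulate_class_spectra("dermis", 30, library, cfg, seed=5)
                   + simulate_class_spectra("fat", 6, library, cfg, seed=6))
        x, axis = self._normalized(spectra)
        a = cl.pca_screen(x, library, axis=axis)
        b = cl.pca_screen(x, library, axis=axis)
        assert np.array_equal(a, b)

    def test_too_few_spectra_rejected(self, library):
        with pytest.raises(ValueError, match=">= 10"):
            cl.pca_screen(np.zeros((5, 100)), library)


class TestClusterReferenceMap:
    def test_two_class_raster_map_recovered(self, library, cfg):
        """Simulated 2-class raster map clusters to >= 99% agreement after
        label permutation."""
        a = simulate_class_spectra("dermis", 60, library, cfg, seed=0)
        b = simulate_class_spectra("fat", 40, library, cfg, seed=1)
        x = np.array([ro.snv_normalize(ro.crop_range(
            s, *ro.CLASSIFY_RANGE_CM1)).intensity for s in a + b])
        lab = cl.cluster_reference_map(x, k=2, seed=0)
        truth = np.array([0] * 60 + [1] * 40)
        agree = max(np.mean(lab == truth), np.mean(lab == 1 - truth))
        assert agree >= 0.99

    def test_k_one_single_label_and_grid_shape(self):
        x = np.random.default_rng(0).normal(size=(64, 10))
        lab = cl.cluster_reference_map(x, k=1, grid_shape=(8, 8))
        assert lab.shape == (8, 8)
        assert np.all(lab == 0)

    def test_seeded_determinism(self):
        x = np.random.default_rng(1).normal(size=(50, 8))
        assert np.array_equal(cl.cluster_reference_map(x, 3, seed=5),
                              cl.cluster_reference_map(x, 3, seed=5))


def make_separable_features(n=120, seed=0):
    rng = np.random.default_rng(seed)
    means = {"BCC": [3, 0, 0, 3, -1], "epidermis": [0, 0, -1, 0, 2],
             "dermis": [0, 2, -5, 0, -2]}
    x, y = [], []
    for cname, mu in means.items():
        x.append(rng.normal(mu, 0.05, size=(n, 5)))
        y += [cname] * n
    return np.vstack(x), np.array(y, dtype=object)


class TestTrainClassifier:
    def test_separable_classes_perfect_cv(self):
        x, y = make_separable_features()
        model = cl.train_classifier(x, y, seed=0)
        rep = model.cv_report[model.cv_report.C == model.C]
        assert rep.sensitivity.mean() >= 0.95
        assert rep.specificity.mean() == 1.0
        calls, _ = model.classify(x)
        assert np.mean(calls == y) > 0.95

    def test_regularization_choice_matches_grid_oracle(self):
        x, y = make_separable_features(seed=3)
        model = cl.train_classifier(x, y, seed=1)
        rep = model.cv_report
        means = rep.groupby("C")[["sensitivity", "specificity"]].mean()
        ok = means[means.sensitivity >= 0.95]
        assert model.C == float(ok.specificity.idxmax())

    def test_missing_class_rejected(self):
        x, y = make_separable_features()
        with pytest.raises(ValueError, match="3 classes"):
            cl.train_classifier(x[y != "dermis"], y[y != "dermis"], seed=0)

    def test_probabilities_sum_to_one(self):
        x, y = make_separable_features()
        model = cl.train_classifier(x, y, seed=0)
        p = model.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_threshold_rule_matches_stored_weights(self):
        x, y = make_separable_features(seed=5)
        model = cl.train_classifier(x, y, seed=2)
        calls, p_bcc = model.classify(x)
        i = model.classes.index("BCC")
        z = model._standardize(x) @ model.coef.T + model.intercept
        p = np.exp(z - z.max(axis=1, keepdims=True))
        p = p / p.sum(axis=1, keepdims=True)
        assert np.allclose(p_bcc, p[:, i], atol=1e-12)
        assert np.array_equal(calls == "BCC", p[:, i] >= model.threshold)

    def test_json_roundtrip(self, tmp_path):
        x, y = make_separable_features()
        model = cl.train_classifier(x, y, seed=0)
        model.to_json(tmp_path / "m.json")
        back = cl.ClassifierModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.predict_proba(x), model.predict_proba(x))
        assert back.threshold == model.threshold


class TestSegmentAveraging:
    def _model(self):
        x, y = make_separable_features()
        return cl.train_classifier(x, y, seed=0)

    def _spectra(self, library, cfg, cname, n, seed):
        out = []
        for s in simulate_class_spectra(cname, n, library, cfg, seed=seed):
            out.append(ro.snv_normalize(ro.crop_range(
                s, *ro.CLASSIFY_RANGE_CM1)))
        return out

    def test_identical_spectra_average_equals_single(self, library,
                                                     quiet_cfg):
        model = self._model()
        s = self._spectra(library, quiet_cfg, "dermis", 1, 0)[0]
        single = cl.segment_average_classify({1: [s]}, model)
        triple = cl.segment_average_classify({1: [s, s, s]}, model)
        assert single.calls.iloc[0].call == triple.calls.iloc[0].call
        assert single.calls.iloc[0].p_bcc == pytest.approx(
            triple.calls.iloc[0].p_bcc)

    def test_average_noise_shrinks_like_sqrt_n(self, library, cfg):
        """Residual noise SD of a 9-average is ~ sigma/3.

        The mean spectrum is dominated by band structure, so the noise is
        measured from differences between independent replicates, where the
        structure cancels exactly.
        """
        diffs, singles = [], []
        for rep in range(60):
            a = np.array([s.intensity for s in simulate_class_spectra(
                "dermis", 9, library, cfg, seed=rep)])
            b = np.array([s.intensity for s in simulate_class_spectra(
                "dermis", 9, library, cfg, seed=10_000 + rep)])
            diffs.append((a.mean(axis=0) - b.mean(axis=0)).std())
            singles.append((a[0] - b[0]).std())
        shrink = np.mean(singles) / np.mean(diffs)
        assert shrink == pytest.approx(3.0, rel=0.2)

    def test_all_saturated_segment_unmeasured(self, library, quiet_cfg):
        model = self._model()
        s = self._spectra(library, quiet_cfg, "dermis", 1, 0)[0]
        sat = dataclasses.replace(s)
        sat.saturated = True
        out = cl.segment_average_classify({1: [sat, sat]}, model)
        assert out.calls.iloc[0].call == "none"
        assert out.calls.iloc[0].n_spectra == 0

    def test_majority_screen_flag_calls_segment_directly(self, library,
                                                         quiet_cfg):
        model = self._model()
        s = self._spectra(library, quiet_cfg, "fat", 1, 0)[0]
        out = cl.segment_average_classify(
            {1: [s, s, s]}, model,
            screen_labels={1: np.array(["fat", "fat", "keep"], dtype=object)})
        assert out.calls.iloc[0].call == "fat"
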