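"""Detection pipeline: preprocessing, xDAWN, features, SVM grid, fusion."""

import numpy as np
import pytest

from errpbandit.errp import (
    C_GRID,
    CLASS_WEIGHT_GRID,
    DEFAULT_WINDOWS,
    ErrPDetector,
    WindowSpec,
    apply_spatial_filter,
    extract_features,
    fit_xdawn,
    fuse_decisions,
    preprocess,
    train_classifier,
)
from errpbandit.synthdata import EEGEpoch, gen_epoch


class TestPreprocess:
    @pytest.mark.parametrize("srate", [250, 5000])
    def test_window_comes_out_as_35_samples_at_50hz(self, srate, rng):
        ep = gen_epoch("Corr", n_channels=4, srate=srate, rng=rng)
        out = preprocess(ep, WindowSpec(0.0, 0.7))
        assert out.data.shape == (4, 35)
        assert out.srate == 50
        assert out.t0_offset == 0.0

    def test_constant_channel_becomes_zero(self):
        data = np.vstack([np.full(275, 7.3), np.zeros(275)])
        ep = EEGEpoch(data=data, srate=250, t0_offset=-0.1, label="Corr")
        out = preprocess(ep, WindowSpec(-0.1, 0.6))
        np.testing.assert_allclose(out.data[0], 0.0, atol=1e-9)

    def test_stopband_attenuation_vs_passband(self):
        # a 20 Hz tone must come out >= 20 dB weaker than a 5 Hz tone of
        # equal amplitude (both survive decimation to 50 Hz)
        t = np.arange(275) / 250 - 0.1
        powers = {}
        for f in (5.0, 20.0):
            ep = EEGEpoch(data=np.sin(2 * np.pi * f * t)[None, :], srate=250, t0_offset=-0.1, label="Corr")
            out = preprocess(ep, WindowSpec(-0.1, 0.6))
            powers[f] = np.mean(out.data**2)
        assert 10 * np.log10(powers[5.0] / powers[20.0]) >= 20

    def test_window_outside_span_rejected(self, rng):
        ep = gen_epoch("Corr", n_channels=2, rng=rng)
        with pytest.raises(ValueError, match="outside epoch span"):
            preprocess(ep, WindowSpec(0.5, 1.2))


class TestXdawn:
    def test_projection_shape_64_to_8(self, rng):
        epochs = [gen_epoch(lbl, n_channels=64, rng=rng) for lbl in ["Err"] * 5 + ["Corr"] * 15]
        filt = fit_xdawn(epochs, n_components=8)
        assert filt.projection.shape == (64, 8)
        filtered = apply_spatial_filter(filt, epochs[0])
        assert filtered.data.shape == (8, epochs[0].n_samples)

    def test_linearity_zero_in_zero_out(self, rng):
        epochs = [gen_epoch(lbl, n_channels=8, rng=rng) for lbl in ["Err"] * 4 + ["Corr"] * 8]
        filt = fit_xdawn(epochs, n_components=3)
        zero = EEGEpoch(data=np.zeros((8, 100)), srate=250, t0_offset=0.0, label="Corr")
        np.testing.assert_array_equal(apply_spatial_filter(filt, zero).data, 0.0)

    def test_first_component_recovers_template(self, rng):
        # nearly noise-free rank-one evoked structure: the leading filter's
        # output on an Err epoch must reproduce the template time course
        n_ch, n_t = 12, 200
        topo = rng.normal(size=n_ch)
        template = np.sin(2 * np.pi * 3 * np.arange(n_t) / n_t)
        eps = 1e-4
        epochs = []
        for lbl in ["Err"] * 6 + ["Corr"] * 12:
            noise = eps * rng.standard_normal((n_ch, n_t))
            data = noise + (np.outer(topo, template) if lbl == "Err" else 0.0)
            epochs.append(EEGEpoch(data=data, srate=250, t0_offset=0.0, label=lbl))
        filt = fit_xdawn(epochs, n_components=2)
        out = filt.projection[:, 0] @ epochs[0].data
        assert abs(np.corrcoef(out, template)[0, 1]) > 0.99

    def test_single_class_rejected(self, rng):
        epochs = [gen_epoch("Corr", n_channels=4, rng=rng) for _ in range(6)]
        with pytest.raises(ValueError, match="both Err and Corr"):
            fit_xdawn(epochs)


class TestFeatures:
    @pytest.mark.parametrize("n_comp,expected", [(1, 35), (2, 70), (8, 280)])
    def test_feature_count_scales_with_components(self, n_comp, expected):
        ep = EEGEpoch(data=np.arange(n_comp * 35, dtype=float).reshape(n_comp, 35),
                      srate=50, t0_offset=0.0, label="Corr")
        feats = extract_features(ep, WindowSpec(0.0, 0.7))
        assert feats.shape == (expected,)
        # row-major: first 35 entries are channel 0's time course
        np.testing.assert_array_equal(feats[:35], ep.data[0])

    def test_shape_mismatch_rejected(self):
        ep = EEGEpoch(data=np.zeros((2, 30)), srate=50, t0_offset=0.0, label="Corr")
        with pytest.raises(ValueError, match="time samples"):
            extract_features(ep, WindowSpec(0.0, 0.7))


class TestClassifier:
    def test_separable_features_reach_perfect_cv_bacc(self, rng):
        X = np.vstack([rng.normal(5, 0.1, (20, 6)), rng.normal(-5, 0.1, (60, 6))])
        y = ["Err"] * 20 + ["Corr"] * 60
        clf = train_classifier(X, y, seed=0)
        assert clf.cv_bacc == 1.0

    def test_label_shuffle_drops_to_chance(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(5, 0.1, (30, 6)), rng.normal(-5, 0.1, (90, 6))])
        y = np.array([1] * 30 + [0] * 90)
        rng.shuffle(y)
        clf = train_classifier(X, y, seed=0)
        assert 0.3 < clf.cv_bacc < 0.7

    def test_grid_has_35_cells(self, rng):
        assert len(C_GRID) * len(CLASS_WEIGHT_GRID) == 35
        X = np.vstack([rng.normal(1, 1, (10, 4)), rng.normal(-1, 1, (40, 4))])
        clf = train_classifier(X, [1] * 10 + [0] * 40, seed=0)
        assert len(clf.grid_scores) == 35

    def test_minority_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        with pytest.raises(ValueError, match="minority class"):
            train_classifier(X, [1] * 3 + [0] * 17, seed=0)

    def test_json_roundtrip(self, tmp_path, rng):
        X = np.vstack([rng.normal(2, 1, (10, 4)), rng.normal(-2, 1, (40, 4))])
        clf = train_classifier(X, [1] * 10 + [0] * 40, seed=0)
        clf.to_json(tmp_path / "clf.json")
        from errpbandit.errp import ErrPClassifier

        clf2 = ErrPClassifier.from_json(tmp_path / "clf.json")
        f = rng.normal(size=4)
        assert clf.score(f) == pytest.approx(clf2.score(f))


class TestFusion:
    @pytest.mark.parametrize(
        "d1,d2,reward", [(False, False, 1), (True, False, 0), (False, True, 0), (True, True, 0)]
    )
    def test_reward_only_on_double_no_errp(self, d1, d2, reward):
        assert fuse_decisions(d1, d2) == reward


class TestDetectorEndToEnd:
    def test_fit_and_detect_on_small_set(self, small_epoch_set):
        det = ErrPDetector(n_components=4, seed=0).fit(small_epoch_set)
        assert det.spatial_filter.projection.shape == (16, 4)
        d1, d2 = det.detect(small_epoch_set[0])
        assert isinstance(d1, (bool, np.bool_)) and isinstance(d2, (bool, np.bool_))
        assert det.reward(small_epoch_set[0]) in (0, 1)

    def test_pipeline_deterministic_given_seed(self, small_epoch_set):
        d1 = ErrPDetector(n_components=4, seed=5).fit(small_epoch_set)
        d2 = ErrPDetector(n_components=4, seed=5).fit(small_epoch_set)
        np.testing.assert_allclose(d1.classifier.weights, d2.classifier.weights)
        assert d1.classifier.chosen_C == d2.classifier.chosen_C

    def test_unfitted_detector_refuses_to_decide(self, rng):
        det = ErrPDetector()
        with pytest.raises(RuntimeError, match="not fitted"):
            det.detect(gen_epoch("Corr", n_channels=4, rng=rng))
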