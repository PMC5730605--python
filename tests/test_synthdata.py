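"""Generator correctness: archetypes, ERP structure, schedules, determinism."""

import numpy as np
import pytest
from scipy import stats

from errpbandit.synthdata import (
    ARCHETYPES,
    GESTURE_IDS,
    erp_template,
    erp_topography,
    gen_epoch,
    gen_gesture,
    gen_schedule,
    load_epochs,
    save_epochs,
)


class TestGestures:
    @pytest.mark.parametrize("gesture", GESTURE_IDS)
    def test_zero_noise_returns_archetype(self, gesture, rng):
        g = gen_gesture(gesture, noise_sd=0.0, rng=rng)
        np.testing.assert_allclose(g.as_vector(), ARCHETYPES[gesture])
        assert g.as_vector().shape == (4,)

    def test_grab_strength_always_in_unit_interval(self, rng):
        for _ in range(200):
            g = gen_gesture("forward", noise_sd=0.5, rng=rng)
            assert 0.0 <= g.grab_strength <= 1.0

    def test_monte_carlo_mean_recovers_archetype(self, rng):
        # 10k draws of the 10-subsample average; palm components are
        # unclipped so their sample mean must sit within 4 SE of the
        # archetype.  The grab component is compared against the analytic
        # clipped-normal mean (clipping at 0 biases it slightly upward).
        n, sd = 10_000, 0.05
        draws = np.stack([gen_gesture("left", noise_sd=sd, rng=rng).as_vector() for _ in range(n)])
        se = sd / np.sqrt(10) / np.sqrt(n)
        np.testing.assert_allclose(draws[:, :3].mean(axis=0), ARCHETYPES["left"][:3], atol=4 * se)
        mu = ARCHETYPES["left"][3]
        a, b = (0 - mu) / sd, (1 - mu) / sd
        # E[clip(X,0,1)] for X ~ N(mu, sd)
        clipped_mean = (
            mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
            + sd * (stats.norm.pdf(a) - stats.norm.pdf(b))
            + 0 * stats.norm.cdf(a)
            + 1 * stats.norm.sf(b)
        )
        assert abs(draws[:, 3].mean() - clipped_mean) < 4 * se

    def test_unknown_gesture_rejected(self, rng):
        with pytest.raises(ValueError, match="gesture_id"):
            gen_gesture("wave", rng=rng)


class TestEpochs:
    def test_correct_epochs_are_zero_mean_noise(self, rng):
        ep = gen_epoch("Corr", snr=5.0, n_channels=16, rng=rng)
        assert ep.label == "Corr"
        assert ep.n_samples == round(1.1 * ep.srate)
        # no template: channel means within CLT bounds of zero
        se = 1.0 / np.sqrt(ep.n_samples)
        assert np.all(np.abs(ep.data.mean(axis=1)) < 5 * se)

    def test_noiseless_limit_matches_template(self, rng):
        ep = gen_epoch("Err", snr=1e6, jitter_sd=0.0, n_channels=16, rng=rng)
        ch = int(np.argmax(erp_topography(16)))
        template = erp_template(ep.times)
        r = np.corrcoef(ep.data[ch], template)[0, 1]
        assert r > 0.9999

    def test_grand_average_recovers_peak_latency(self):
        # averaging over jittered single trials must put the positive peak
        # of the grand average within one jitter sd of its true latency
        rng = np.random.default_rng(7)
        jitter_sd = 0.05
        n_channels, n_epochs = 16, 500
        acc = None
        for _ in range(n_epochs):
            ep = gen_epoch("Err", snr=1.0, jitter_sd=jitter_sd, n_channels=n_channels, rng=rng)
            acc = ep.data if acc is None else acc + ep.data
        grand = acc / n_epochs
        ch = int(np.argmax(erp_topography(n_channels)))
        times = np.arange(grand.shape[1]) / 250 - 0.1
        peak_t = times[np.argmax(grand[ch])]
        assert abs(peak_t - 0.30) <= jitter_sd

    def test_invalid_arguments_rejected(self, rng):
        with pytest.raises(ValueError):
            gen_epoch("Err", srate=0, rng=rng)
        with pytest.raises(ValueError):
            gen_epoch("Maybe", rng=rng)
        with pytest.raises(ValueError):
            gen_epoch("Err", snr=-1, rng=rng)


class TestSchedules:
    def test_training_default_ratio(self, rng):
        s = gen_schedule("training", 90, 10, rng=rng)
        assert s.n_err == 10
        assert s.labels().count("Corr") == 80

    def test_all_correct_schedule(self, rng):
        s = gen_schedule("training", 90, 0, rng=rng)
        assert s.n_err == 0

    def test_error_fraction_over_many_schedules(self, rng):
        # counts are exact per schedule, so the pooled fraction is exactly 1/9
        total_err = sum(gen_schedule("training", 90, 10, rng=rng).n_err for _ in range(120))
        assert total_err / (120 * 90) == pytest.approx(10 / 90)

    def test_too_many_errors_rejected(self, rng):
        with pytest.raises(ValueError):
            gen_schedule("training", 9, 10, rng=rng)


class TestDeterminismAndIO:
    def test_identical_seeds_reproduce_everything(self):
        def draw(seed):
            rng = np.random.default_rng(seed)
            g = gen_gesture("right", rng=rng)
            e = gen_epoch("Err", n_channels=8, rng=rng)
            s = gen_schedule("training", 90, 10, rng=rng)
            return g, e, s

        g1, e1, s1 = draw(42)
        g2, e2, s2 = draw(42)
        np.testing.assert_array_equal(g1.as_vector(), g2.as_vector())
        np.testing.assert_array_equal(e1.data, e2.data)
        assert e1.latency_jitter == e2.latency_jitter
        assert s1.err_positions == s2.err_positions

    def test_epoch_hdf5_roundtrip(self, tmp_path, rng):
        epochs = [gen_epoch(lbl, n_channels=8, rng=rng) for lbl in ("Err", "Corr", "Corr")]
        save_epochs(tmp_path / "e.h5", epochs)
        loaded = load_epochs(tmp_path / "e.h5")
        assert [e.label for e in loaded] == ["Err", "Corr", "Corr"]
        np.testing.assert_allclose(loaded[0].data, epochs[0].data)
        assert loaded[0].srate == epochs[0].srate


def test_pink_noise_option_tilts_spectrum_low():
    """With the 1/f component enabled, relative power below 5 Hz rises."""

    def low_fraction(pink):
        ep = gen_epoch("Corr", n_channels=4, rng=np.random.default_rng(2), pink=pink)
        spec = np.abs(np.fft.rfft(ep.data, axis=1)) ** 2
        f = np.fft.rfftfreq(ep.n_samples, 1 / ep.srate)
        return spec[:, f < 5].sum() / spec.sum()

    assert low_fraction(2.0) > low_fraction(0.0) + 0.1
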