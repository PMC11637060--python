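"""RF conditioning chain: closed-form gains, resampling, noise statistics."""

import numpy as np
import pytest

from echosos import rfpipe as rp
from echosos.wavesim import RFFrame, RF_RATE_HZ, ProbeGeometry


def frame(data, fs=RF_RATE_HZ):
    return RFFrame(np.asarray(data, dtype=np.float64), fs)


class TestTGC:
    def test_gain_at_zero_time_is_one(self):
        rf = frame(np.ones((4, 100)))
        out = rp.apply_tgc(rf, 0.5, 1540.0, 7e6)
        assert out.data[0, 0] == pytest.approx(1.0)

    def test_gain_at_one_cm_depth(self):
        # t = 2 * 1 cm / 1540 m/s: gain = 10^(0.5 * 7 * 1 / 20) ~ 1.496
        fs = 100e6
        t_target = 2 * 0.01 / 1540.0
        n = int(round(t_target * fs))
        rf = frame(np.ones((1, n + 1)), fs)
        out = rp.apply_tgc(rf, 0.5, 1540.0, 7e6)
        assert out.data[0, n] == pytest.approx(10 ** 0.175, rel=1e-3)

    def test_zero_alpha_identity(self):
        rf = frame(np.random.default_rng(0).standard_normal((4, 64)))
        out = rp.apply_tgc(rf, 0.0)
        assert np.allclose(out.data, rf.data)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            rp.apply_tgc(frame(np.ones((1, 8))), -0.1)


class TestDownsample:
    def test_factor_five_shape(self):
        rf = frame(np.random.default_rng(0).standard_normal((128, 5120)), 100e6)
        out = rp.downsample_to_20mhz(rf)
        assert out.data.shape == (128, 1024)
        assert out.sample_rate_hz == RF_RATE_HZ

    def test_passband_tone_preserved(self):
        fs = 100e6
        t = np.arange(5120) / fs
        rf = frame(np.sin(2 * np.pi * 3e6 * t)[None, :], fs)
        out = rp.downsample_to_20mhz(rf)
        mid = out.data[0, 100:900]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_rejected(self):
        fs = 100e6
        t = np.arange(5120) / fs
        rf = frame(np.sin(2 * np.pi * 12e6 * t)[None, :], fs)
        out = rp.downsample_to_20mhz(rf)
        atten = np.abs(out.data[0, 100:900]).max()
        assert 20 * np.log10(atten / 1.0) < -40.0

    def test_below_rf_clock_rejected(self):
        with pytest.raises(ValueError):
            rp.downsample_to_20mhz(frame(np.ones((1, 100)), 10e6))


class TestZeroAndNormalize:
    def test_zero_early_row_sums(self):
        rf = frame(np.ones((128, 1024)))
        out = rp.zero_early_samples(rf, 50)
        assert np.all(out.data.sum(axis=1) == 974)

    def test_zero_early_idempotent_and_identity(self):
        rf = frame(np.random.default_rng(1).standard_normal((8, 128)))
        once = rp.zero_early_samples(rf, 20)
        twice = rp.zero_early_samples(once, 20)
        assert np.array_equal(once.data, twice.data)
        assert np.array_equal(rp.zero_early_samples(rf, 0).data, rf.data)

    def test_zero_entire_frame_rejected(self):
        with pytest.raises(ValueError):
            rp.zero_early_samples(frame(np.ones((2, 10))), 10)

    def test_normalize_moments_and_idempotence(self):
        rf = frame(np.random.default_rng(2).uniform(-3, 7, (128, 1024)))
        out = rp.normalize_channels(rf)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-6
        assert np.abs(out.data.std(axis=1) - 1).max() < 1e-6
        again = rp.normalize_channels(out)
        assert np.allclose(again.data, out.data, atol=1e-9)

    def test_constant_channel_flagged(self):
        data = np.random.default_rng(3).standard_normal((4, 64))
        data[2] = 5.0
        out = rp.normalize_channels(frame(data))
        assert np.all(out.data[2] == 0)
        assert out.meta["dead_channels"] == [2]


class TestThermalNoise:
    def test_infinite_snr_identity(self):
        rf = frame(np.random.default_rng(4).standard_normal((8, 256)))
        out = rp.add_thermal_noise(rf, np.inf, seed=0)
        assert np.array_equal(out.data, rf.data)

    def test_measured_snr_matches_drawn(self):
        rf = frame(np.random.default_rng(5).standard_normal((128, 1024)))
        snr = 50.0
        out = rp.add_thermal_noise(rf, snr, seed=7)
        noise = out.data - rf.data
        measured = 10 * np.log10((rf.data ** 2).mean() / (noise ** 2).mean())
        assert measured == pytest.approx(snr, abs=0.5)

    def test_seeds_differ_power_matches(self):
        rf = frame(np.random.default_rng(6).standard_normal((64, 1024)))
        n1 = rp.add_thermal_noise(rf, 45.0, seed=1).data - rf.data
        n2 = rp.add_thermal_noise(rf, 45.0, seed=2).data - rf.data
        assert not np.array_equal(n1, n2)
        assert (n1 ** 2).mean() == pytest.approx((n2 ** 2).mean(), rel=0.10)

    def test_snr_draw_bounds(self):
        draws = [rp.draw_thermal_snr(s) for s in range(200)]
        assert min(draws) >= 40.0 and max(draws) <= 80.0
        with pytest.raises(ValueError):
            rp.draw_thermal_snr(0, 80.0, 40.0)


class TestSystemNoise:
    def test_disabled_identity(self):
        rf = frame(np.random.default_rng(7).standard_normal((8, 256)))
        assert np.array_equal(rp.add_system_noise(rf, None, 0).data, rf.data)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            rp.add_system_noise(frame(np.ones((2, 64))), np.empty((0, 50)), 0)

    def test_early_window_rms_additivity(self):
        rng = np.random.default_rng(8)
        rf = frame(rng.standard_normal((32, 1024)) * 0.01)
        bank = rp.synthetic_noise_bank(n_segments=1, seed=5)
        out = rp.add_system_noise(rf, bank, seed=1, amplitude=3.0)
        added = out.data[:, :50] - rf.data[:, :50]
        # independent additive burst: energies add
        rms_before = np.sqrt((rf.data[:, :50] ** 2).mean())
        rms_added = np.sqrt((added ** 2).mean())
        rms_after = np.sqrt((out.data[:, :50] ** 2).mean())
        assert rms_added > 0
        assert rms_after == pytest.approx(np.hypot(rms_before, rms_added), rel=0.05)
        assert np.array_equal(out.data[:, 50:], rf.data[:, 50:])

    def test_seeded_draw_reproducible(self):
        rf = frame(np.random.default_rng(9).standard_normal((8, 256)))
        bank = rp.synthetic_noise_bank(seed=5)
        a = rp.add_system_noise(rf, bank, seed=3).data
        b = rp.add_system_noise(rf, bank, seed=3).data
        assert np.array_equal(a, b)


class TestFullChain:
    def test_contract_on_solver_like_rf(self):
        rng = np.random.default_rng(10)
        raw = frame(rng.standard_normal((128, 4096)) *
                    np.exp(-np.arange(4096) / 2000)[None, :], 80e6)
        out = rp.condition(raw, seed=11)
        assert out.data.shape == (128, 1024)
        assert np.isfinite(out.data).all()
        assert np.abs(out.data.mean(axis=1)).max() < 1e-6
        assert np.allclose(out.data.std(axis=1), 1.0, atol=1e-6)
        assert not out.data[:, :50].any()
        assert out.meta["pipeline_order"][-1] == "normalize"

    def test_chain_reproducible_from_seed(self):
        rng = np.random.default_rng(12)
        raw = frame(rng.standard_normal((128, 2048)), 40e6)
        a = rp.condition(raw, seed=21).data
        b = rp.condition(raw, seed=21).data
        assert np.array_equal(a, b)


class TestDomainShift:
    def test_output_standardized_and_different(self):
        rng = np.random.default_rng(13)
        base = rp.normalize_channels(frame(rng.standard_normal((128, 1024))))
        shifted = rp.domain_shift(base, seed=4)
        assert shifted.data.shape == (128, 1024)
        assert np.abs(shifted.data.mean(axis=1)).max() < 1e-6
        assert not np.allclose(shifted.data, base.data)


class TestBMode:
    def test_point_scatterer_localized(self, scatterer_rf_128):
        fx = scatterer_rf_128
        rf = rp.downsample_to_20mhz(fx["rf"], n_out=1024)
        rf = rp.zero_early_samples(rf, 300)  # blank crosstalk + near-field reverb
        pix = 0.1
        img = rp.das_bmode(rf, fx["c"], fx["probe"], image_shape=(384, 384),
                           pixel_mm=pix, f_number=1.5)
        r, c = np.unravel_index(np.argmax(img), img.shape)
        z_mm = (r + 0.5) * pix
        x_mm = (c + 0.5) * pix - 384 * pix / 2
        assert abs(z_mm - fx["depth_mm"]) < 0.6
        assert abs(x_mm - fx["x_mm"]) < 0.6

    def test_wrong_sos_displaces_axially(self, scatterer_rf_128):
        fx = scatterer_rf_128
        rf = rp.downsample_to_20mhz(fx["rf"], n_out=1024)
        rf = rp.zero_early_samples(rf, 300)
        pix = 0.1

        def peak_depth(c):
            img = rp.das_bmode(rf, c, fx["probe"], image_shape=(384, 384),
                               pixel_mm=pix, f_number=1.5)
            r, _ = np.unravel_index(np.argmax(img), img.shape)
            return (r + 0.5) * pix

        # ~5 % deeper apparent depth under a 5 % faster assumed speed
        shift = peak_depth(fx["c"] * 1.05) - peak_depth(fx["c"])
        assert shift == pytest.approx(0.05 * fx["depth_mm"], abs=0.4)

    def test_zero_rf_floored_image(self):
        rf = RFFrame(np.zeros((128, 1024)), RF_RATE_HZ)
        img = rp.das_bmode(rf, 1540.0, ProbeGeometry(), image_shape=(64, 64))
        assert np.all(img == -50.0)

    def test_implausible_sos_warns(self):
        rf = RFFrame(np.zeros((128, 128)), RF_RATE_HZ)
        with pytest.warns(UserWarning):
            rp.das_bmode(rf, 1200.0, ProbeGeometry(), image_shape=(16, 16))
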