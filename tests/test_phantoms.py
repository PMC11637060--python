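"""Phantom generator: sampling laws, rasterization geometry, labels."""

import numpy as np
import pytest
from scipy import stats

from echosos import phantoms as ph


class TestSampling:
    def test_background_law_uniform_1400_1600(self):
        draws = np.array([ph.sample_training_phantom(s).background_sos
                          for s in range(2000)])
        assert draws.min() >= 1400.0 and draws.max() <= 1600.0
        assert abs(draws.mean() - 1500.0) < 5.0
        p = stats.kstest(draws, stats.uniform(1400, 200).cdf).pvalue
        assert p > 1e-3

    def test_inclusion_sos_one_to_seven_percent_above_background(self):
        for s in range(200):
            spec = ph.sample_training_phantom(s)
            for inc in spec.inclusions:
                ratio = inc.sos / spec.background_sos
                assert 1.01 - 1e-12 <= ratio <= 1.07 + 1e-12

    def test_spec_deterministic_and_json_roundtrip(self):
        a = ph.sample_training_phantom(42)
        b = ph.sample_training_phantom(42)
        assert a.to_json() == b.to_json()
        assert ph.PhantomSpec.from_json(a.to_json()).to_json() == a.to_json()

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ph.sample_training_phantom(0, ph.TrainingBounds(sos_min=1600, sos_max=1400))

    def test_scatterer_amplitude_law(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=384)
        # high density so a single draw yields ~1e5 amplitudes
        _, field = ph.sprinkle_scatterers(med, density=70.0, fc_hz=1.5e6, seed=5)
        assert field.amplitudes.size > 5e4
        p = stats.kstest(field.amplitudes, stats.uniform(-0.03, 0.06).cdf).pvalue
        assert p > 1e-3

    def test_scatterer_count_matches_density(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1540.0), n=256)
        fc = 7e6
        lam_mm = 1540.0 / fc * 1e3
        expected = 3.0 * ph.EXTENT_MM ** 2 / lam_mm ** 2
        _, field = ph.sprinkle_scatterers(med, density=3.0, fc_hz=fc, seed=0)
        assert abs(field.amplitudes.size - expected) < 3 * np.sqrt(expected)

    def test_zero_density_is_identity(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=128)
        out, field = ph.sprinkle_scatterers(med, density=0.0, fc_hz=7e6, seed=0)
        assert np.array_equal(out.density, med.density)
        assert field.amplitudes.size == 0

    def test_negative_density_rejected(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=128)
        with pytest.raises(ValueError):
            ph.sprinkle_scatterers(med, density=-1.0, fc_hz=7e6, seed=0)


class TestRasterization:
    def test_homogeneous_spec_constant_field(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1540.0), n=256)
        assert np.all(med.sos == 1540.0)
        assert np.all(med.density == 1020.0)
        assert np.all(med.attenuation == 0.5)

    def test_full_grid_extent(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=1536)
        assert med.shape == (1536, 1536)
        assert med.dx_mm == pytest.approx(0.025)
        assert med.shape[0] * med.dx_mm == pytest.approx(38.4)

    def test_circle_pixel_count_matches_area(self):
        r_mm = 5.0
        spec = ph.PhantomSpec(background_sos=1500.0, inclusions=[
            ph.EllipseInclusion((0.0, 19.2), (r_mm, r_mm), 0.0, 1550.0)])
        med = ph.rasterize_medium(spec, n=1536)
        count = int((med.sos == 1550.0).sum())
        r_px = r_mm / med.dx_mm
        area = np.pi * r_px ** 2
        perimeter = 2 * np.pi * r_px
        assert abs(count - area) < perimeter

    def test_later_inclusions_overwrite(self):
        e1 = ph.EllipseInclusion((0.0, 19.2), (6.0, 6.0), 0.0, 1550.0)
        e2 = ph.EllipseInclusion((0.0, 19.2), (3.0, 3.0), 0.0, 1580.0)
        med = ph.rasterize_medium(ph.PhantomSpec(1500.0, [e1, e2]), n=256)
        center = med.sos[med.shape[0] // 2, med.shape[1] // 2]
        assert center == 1580.0

    def test_extent_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=256,
                                dx_mm=0.1)


class TestEchogenicity:
    def test_hyperechoic_fraction_and_range(self):
        inc = ph.EllipseInclusion((0.0, 19.2), (8.0, 8.0), 0.0, 1530.0,
                                  echogenicity="hyperechoic")
        spec = ph.PhantomSpec(1500.0, [inc])
        med = ph.rasterize_medium(spec, n=512)
        out = ph.apply_echogenicity(med, spec, seed=3)
        mask = ph.ellipse_mask(inc, 512, med.dx_mm)
        changed = (out.sos != med.sos) & mask
        frac = changed.sum() / mask.sum()
        assert 0.08 <= frac <= 0.12
        vals = out.sos[changed]
        assert vals.min() >= 1500.0 * 1.07 - 1e-9
        assert vals.max() <= 1500.0 * 1.11 + 1e-9

    def test_isoechoic_untouched(self):
        inc = ph.EllipseInclusion((0.0, 19.2), (8.0, 8.0), 0.0, 1530.0,
                                  echogenicity="isoechoic")
        spec = ph.PhantomSpec(1500.0, [inc])
        med = ph.rasterize_medium(spec, n=256)
        out = ph.apply_echogenicity(med, spec, seed=3)
        assert np.array_equal(out.sos, med.sos)

    def test_hypoechoic_scatterers_dimmed(self):
        inc = ph.EllipseInclusion((0.0, 19.2), (10.0, 10.0), 0.0, 1530.0,
                                  echogenicity="hypoechoic")
        spec = ph.PhantomSpec(1500.0, [inc])
        med = ph.rasterize_medium(spec, n=256)
        out, field = ph.sprinkle_scatterers(med, 3.0, 7e6, seed=0, spec=spec)
        mask = ph.ellipse_mask(inc, 256, med.dx_mm)
        inside = mask[field.rows, field.cols]
        assert np.abs(field.amplitudes[inside]).mean() < \
            np.abs(field.amplitudes[~inside]).mean() * 0.6


class TestLabels:
    def test_constant_medium_constant_label(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1540.0), n=1536)
        label = ph.label_from_medium(med)
        assert label.values.shape == (384, 384)
        assert np.allclose(label.values, 1540.0)

    def test_two_layer_block_mean(self):
        spec = ph.PhantomSpec(1500.0, layers=[ph.LayerInclusion(z0_mm=19.2, sos=1550.0)])
        med = ph.rasterize_medium(spec, n=1536)
        label = ph.label_from_medium(med)
        assert np.allclose(label.values[:192], 1500.0)
        assert np.allclose(label.values[192:], 1550.0)

    def test_region_mean_conserved(self):
        spec = ph.PhantomSpec(1480.0, inclusions=[
            ph.EllipseInclusion((0.0, 20.0), (6.0, 4.0), 0.3, 1530.0)])
        med = ph.rasterize_medium(spec, n=768)
        label = ph.label_from_medium(med)
        # away from boundaries: interior of the inclusion, eroded
        mask = ph.ellipse_mask(ph.EllipseInclusion((0.0, 20.0), (4.0, 2.5), 0.3, 0),
                               384, ph.EXTENT_MM / 384)
        assert abs(label.values[mask].mean() - 1530.0) < 0.5

    def test_incommensurate_shape_rejected(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=512)
        with pytest.raises(ValueError):
            ph.label_from_medium(med)

    def test_desk_grid_upsampled_label(self):
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1460.0), n=128)
        label = ph.label_from_medium(med)
        assert label.values.shape == (384, 384)
        assert np.allclose(label.values, 1460.0)


class TestEvaluationPhantoms:
    def test_batch_of_120(self):
        specs = [ph.make_evaluation_phantom(pat, seed)
                 for pat in (1, 2, 3) for seed in range(40)]
        assert len(specs) == 120
        ids = {s.pattern_id for s in specs}
        assert ids == set(ph.EVAL_PATTERNS)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            ph.make_evaluation_phantom(7, 0)

    def test_pattern1_identical_layer_sos_gives_constant_field(self):
        spec = ph.make_evaluation_phantom(1, 3)
        spec.layers[0].sos = spec.background_sos
        med = ph.rasterize_medium(spec, n=256)
        assert np.ptp(med.sos) == 0.0

    def test_training_phantoms_never_layered(self):
        for s in range(100):
            spec = ph.sample_training_phantom(s)
            assert spec.pattern_id == ph.TRAINING_PATTERN
            assert not spec.layers

    def test_pattern3_hypoechoic_homogeneous_background(self):
        spec = ph.make_evaluation_phantom(3, 11)
        assert all(i.echogenicity == "hypoechoic" for i in spec.inclusions)
        assert spec.layers is None


class TestPointAbsorbers:
    def test_empty_list_zero_field(self):
        p0 = ph.place_point_absorbers([], (128, 128), 0.3)
        assert not p0.any()

    def test_single_point_single_pixel(self):
        p0 = ph.place_point_absorbers([(0.0, 20.0)], (256, 256), 0.15, z0_row=10)
        assert (p0 == 1).sum() == 1
        assert p0.sum() == 1.0

    def test_pencil_lead_disk_area(self):
        # 0.5 mm diameter at 0.05 mm pitch: ~ pi * 5^2 = 79 pixels
        p0 = ph.place_point_absorbers([(0.0, 20.0)], (788, 768), 0.05,
                                      z0_row=10, radius_mm=0.25)
        count = int(p0.sum())
        assert abs(count - np.pi * 25) < 2 * np.pi * 5

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            ph.place_point_absorbers([(0.0, 50.0)], (128, 128), 0.3)


def test_realize_deterministic():
    spec = ph.sample_training_phantom(5)
    a = ph.realize(spec, 128, 1.5e6)
    b = ph.realize(spec, 128, 1.5e6)
    assert np.array_equal(a[1].sos, b[1].sos)
    assert np.array_equal(a[1].density, b[1].density)
    assert np.array_equal(a[2].values, b[2].values)
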