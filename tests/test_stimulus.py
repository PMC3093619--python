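"""Grating, plaid and contour synthesis on the degrees-of-visual-angle grid."""

import math

import numpy as np
import pytest
from scipy import stats

from compadapt import (
    GaussianEnvelope,
    GratingSpec,
    Raster,
    envelope_extent,
    jitter_phase,
    make_contour,
    make_grating,
    make_plaid,
    save_png,
)

RASTER = Raster.square(8.0)


class TestGrating:
    def test_peak_value_equals_contrast(self):
        for contrast in (0.49, 0.2):
            img = make_grating(
                GratingSpec(45.0, 0.8, contrast=contrast), RASTER
            )
            assert np.max(np.abs(img.values)) == pytest.approx(contrast, rel=1e-3)

    def test_zero_contrast_is_blank(self):
        img = make_grating(GratingSpec(45.0, 0.8, contrast=0.0), RASTER)
        assert np.all(img.values == 0.0)

    def test_half_cycle_phase_shift_negates(self):
        a = make_grating(GratingSpec(0.0, 0.8, spatial_phase=0.0), RASTER)
        b = make_grating(GratingSpec(0.0, 0.8, spatial_phase=180.0), RASTER)
        np.testing.assert_allclose(a.values, -b.values, atol=1e-12)

    def test_undersampled_raster_rejected(self):
        with pytest.raises(ValueError, match="under-samples"):
            make_grating(GratingSpec(0.0, 2.0), Raster.square(8.0, pixels_per_degree=6))

    def test_contrast_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GratingSpec(0.0, 0.8, contrast=0.99)
        with pytest.raises(ValueError):
            GratingSpec(0.0, -0.8)


class TestPlaid:
    A = GratingSpec(45.0, 0.8, contrast=0.49)
    B = GratingSpec(-45.0, 0.8, contrast=0.49)
    ENV = GaussianEnvelope(1.33, 1.33)

    def test_linearity(self):
        """The plaid is exactly the sum of the two enveloped gratings."""
        plaid = make_plaid(self.A, self.B, self.ENV, RASTER)
        x, y = RASTER.mesh()
        expected = (
            make_grating(self.A, RASTER).values + make_grating(self.B, RASTER).values
        ) * self.ENV(x, y)
        np.testing.assert_allclose(plaid.values, expected, atol=1e-12)

    def test_peak_contrast_is_component_sum(self):
        # pixel centres sit half a pixel off the exact peak, so the sampled
        # maximum approaches 0.98 from below at sampling resolution
        plaid = make_plaid(self.A, self.B, self.ENV, RASTER)
        peak = np.max(np.abs(plaid.values))
        assert peak == pytest.approx(0.98, abs=0.005)
        assert peak <= 0.98 + 1e-12

    def test_zero_second_component_reduces_to_enveloped_grating(self):
        none = GratingSpec(-45.0, 0.8, contrast=0.0)
        plaid = make_plaid(self.A, none, self.ENV, RASTER)
        x, y = RASTER.mesh()
        np.testing.assert_allclose(
            plaid.values, make_grating(self.A, RASTER).values * self.ENV(x, y),
            atol=1e-12,
        )

    def test_out_of_gamut_contrast_rejected(self):
        hot = GratingSpec(45.0, 0.8, contrast=0.6)
        with pytest.raises(ValueError, match="gamut"):
            make_plaid(hot, hot, self.ENV, RASTER)

    def test_envelope_below_cutoff_beyond_extent_radius(self):
        # at half the 1%-extent diameter the envelope is exactly at cutoff
        r = envelope_extent(1.33, 0.01) / 2.0
        env = self.ENV(np.array([r]), np.array([0.0]))
        assert env[0] == pytest.approx(0.01, rel=1e-9)
        assert self.ENV(np.array([r + 0.1]), np.array([0.0]))[0] < 0.01


class TestEnvelopeExtent:
    @pytest.mark.parametrize(
        "sigma,expected_rounded",
        [(1.33, 8), (1.67, 10), (0.83, 5)],
    )
    def test_printed_stimulus_extents(self, sigma, expected_rounded):
        assert round(envelope_extent(sigma, 0.01)) == expected_rounded

    def test_closed_form_value(self):
        assert envelope_extent(1.33, 0.01) == pytest.approx(
            2 * 1.33 * math.sqrt(2 * math.log(100)), rel=1e-12
        )

    def test_cutoff_near_one_gives_vanishing_extent(self):
        assert envelope_extent(1.33, 1 - 1e-12) == pytest.approx(0.0, abs=1e-4)

    def test_invalid_cutoff_rejected(self):
        for cutoff in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                envelope_extent(1.33, cutoff)

    def test_agrees_with_rendered_image_search(self):
        """Brute-force 1%-of-peak radius on a rendered envelope matches the
        closed form within one pixel."""
        env = GaussianEnvelope(1.33, 1.33)
        raster = Raster.square(12.0)
        x, y = raster.mesh()
        values = env(x, y)
        r = np.hypot(x, y)
        observed = 2 * r[values >= 0.01 * values.max()].max()
        assert abs(observed - envelope_extent(1.33, 0.01)) < 2.0 / raster.pixels_per_degree


class TestContour:
    A = GratingSpec(0.0, 1.1, contrast=0.98)
    ENV = GaussianEnvelope(sigma_x=1.67, sigma_y=0.83)

    def test_straight_contour_is_mirror_symmetric(self):
        img = make_contour(self.A, self.A, self.ENV, apex_angle=180.0)
        np.testing.assert_allclose(img.values, img.values[:, ::-1], atol=1e-12)

    def test_component_swap_mirrors_image(self):
        a = GratingSpec(0.0, 1.1, contrast=0.6)
        b = GratingSpec(0.0, 1.1, contrast=0.3)
        img = make_contour(a, b, self.ENV, apex_angle=140.0)
        swapped = make_contour(b, a, self.ENV, apex_angle=140.0)
        np.testing.assert_allclose(swapped.values, img.values[:, ::-1], atol=1e-12)

    @pytest.mark.parametrize("apex", [60.0, 100.0, 140.0, 179.0])
    def test_mirror_property_holds_for_all_apex_angles(self, apex):
        img = make_contour(self.A, self.A, self.ENV, apex_angle=apex)
        np.testing.assert_allclose(img.values, img.values[:, ::-1], atol=1e-12)

    def test_default_envelope_extent_is_10_by_5_degrees(self):
        w = envelope_extent(self.ENV.sigma_x, 0.01)
        h = envelope_extent(self.ENV.sigma_y, 0.01)
        assert (round(w), round(h)) == (10, 5)

    @pytest.mark.parametrize("apex", [0.0, -10.0, 181.0])
    def test_bad_apex_angle_rejected(self, apex):
        with pytest.raises(ValueError):
            make_contour(self.A, self.A, self.ENV, apex_angle=apex)


class TestJitterPhase:
    def test_reproducible_under_fixed_seed(self):
        spec = GratingSpec(45.0, 0.8)
        seq1 = [jitter_phase(spec, np.random.default_rng(7)).spatial_phase
                for _ in range(1)]
        a = [jitter_phase(spec, rng).spatial_phase
             for rng in [np.random.default_rng(7)]]
        b = [jitter_phase(spec, rng).spatial_phase
             for rng in [np.random.default_rng(7)]]
        assert a == b and seq1 == a

    def test_only_phase_changes(self, rng):
        spec = GratingSpec(45.0, 0.8, spatial_phase=12.0, contrast=0.3)
        out = jitter_phase(spec, rng)
        assert (out.orientation, out.spatial_frequency, out.contrast) == (
            spec.orientation, spec.spatial_frequency, spec.contrast,
        )
        assert 0.0 <= out.spatial_phase < 360.0

    def test_phases_uniform_on_circle(self, rng):
        spec = GratingSpec(45.0, 0.8)
        phases = np.array(
            [jitter_phase(spec, rng).spatial_phase for _ in range(10_000)]
        )
        assert stats.kstest(phases / 360.0, "uniform").pvalue > 0.01


def test_png_export_midgray_is_zero_contrast(tmp_path):
    from PIL import Image

    img = make_grating(GratingSpec(45.0, 0.8, contrast=0.0), Raster.square(2.0))
    out = tmp_path / "blank.png"
    save_png(img, str(out))
    data = np.asarray(Image.open(out))
    assert data.shape == img.values.shape
    assert np.all(data == 128)
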