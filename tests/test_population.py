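"""Population grid, Gabor receptive fields and the position-disparity
cancellation of phase-disparity-induced vertical tuning."""

import numpy as np
import pytest

import stereopop as sp
from stereopop.population import NeuronSpec, image_coords


class TestPositionDisparity:
    def test_no_phase_disparity_no_offset(self):
        for theta in (-60.0, 0.0, 90.0):
            for f in (0.2, 0.025):
                assert sp.position_disparity(6, 0.0, f, theta) == (6.0, 0.0)
                assert sp.position_disparity(0, 0.0, f, theta) == (0.0, 0.0)

    @pytest.mark.parametrize("f", [0.2, 0.0707, 0.025])
    def test_horizontal_unit_vertical_offset_magnitude(self, f):
        # theta = 90 deg: the phase-disparity shift is purely vertical
        # with magnitude (pi/2) / (2 pi f) = 1/(4f)
        dxp, dyp = sp.position_disparity(6, np.pi / 2, f, 90.0)
        assert dxp == pytest.approx(6.0)
        assert abs(dyp) == pytest.approx(1.0 / (4.0 * f))

    def test_offset_is_orthogonal_to_orientation(self):
        theta = 30.0
        dxp, dyp = sp.position_disparity(0, np.pi / 2, 0.1, theta)
        # offset vector is parallel to (cos theta, sin theta)
        th = np.deg2rad(theta)
        cross = dxp * np.sin(th) - dyp * np.cos(th)
        assert cross == pytest.approx(0.0, abs=1e-12)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            sp.position_disparity(0, 0.0, 0.0, 0.0)


class TestGrid:
    def test_degenerate_grid_counts(self):
        cfg = sp.PopulationConfig(
            thetas=(0.0,), freqs=(0.1,), phases=(0.0, np.pi / 2),
            dphis=(0.0,), dx_encs=(0,),
        )
        g = sp.make_population(cfg)
        assert g.n_simple == 2 and g.n_complex == 1

    def test_empty_parameter_list_rejected(self):
        with pytest.raises(ValueError):
            sp.PopulationConfig(thetas=())

    def test_index_param_round_trip(self, small_grid):
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = int(rng.integers(small_grid.n_complex))
            assert small_grid.unit_index(*small_grid.unit_params(i)) == i

    def test_complex_ordering_matches_simple_pairs(self, small_grid):
        # simple cells 2i, 2i+1 are the two phases of complex unit i
        i = 17
        theta, f, dphi, dx_enc = small_grid.unit_params(i)
        for k, phi in enumerate(small_grid.config.phases):
            s = small_grid.simple_cells[2 * i + k]
            assert (s.theta, s.f, s.dphi, s.dx_enc, s.phi) == (
                theta, f, dphi, dx_enc, phi)

    def test_units_hash_tracks_ordering(self, small_grid, small_config):
        g2 = sp.make_population(small_config)
        assert small_grid.units_hash() == g2.units_hash()
        other = sp.make_population(
            sp.PopulationConfig(thetas=(0.0,), freqs=(0.1,))
        )
        assert other.units_hash() != small_grid.units_hash()


class TestGaborRF:
    def test_zero_disparity_eyes_identical(self):
        spec = NeuronSpec.build(30.0, 0.1, 0.0, 0.0, 0)
        left = sp.gabor_rf(spec, "left", (41, 41))
        right = sp.gabor_rf(spec, "right", (41, 41))
        np.testing.assert_array_equal(left, right)

    def test_sigma_scales_with_wavelength(self):
        # sigma = 0.35 * wavelength by default; the factor is configurable
        assert NeuronSpec.build(0.0, 0.200, 0.0, 0.0, 0).sigma == \
            pytest.approx(1.75)
        assert NeuronSpec.build(0.0, 0.025, 0.0, 0.0, 0).sigma == \
            pytest.approx(14.0)
        cfg = sp.PopulationConfig(sigma_factor=0.25)
        assert cfg.sigma(0.2) == pytest.approx(1.25)

    def test_cyclopean_centre_is_origin(self):
        # envelope centroids of the two eyes are symmetric about (0,0)
        spec = NeuronSpec.build(0.0, 0.2, 0.0, np.pi / 2, 5)
        x, y = image_coords((41, 41))
        for eye, sign in (("left", -1.0), ("right", 1.0)):
            rf = np.abs(sp.gabor_rf(spec, eye, (41, 41)))
            cx = (rf * x[None, :]).sum() / rf.sum()
            cy = (rf * y[:, None]).sum() / rf.sum()
            assert cx == pytest.approx(sign * spec.dx_pos / 2, abs=0.05)
            assert cy == pytest.approx(sign * spec.dy_pos / 2, abs=0.05)

    def test_carrier_varies_orthogonal_to_orientation(self):
        # theta = 0 (vertical): rows are identical near the centre, columns
        # oscillate at the carrier frequency
        spec = NeuronSpec.build(0.0, 0.2, 0.0, 0.0, 0)
        rf = sp.gabor_rf(spec, "left", (41, 41))
        mid = rf[20, :]
        assert np.argmax(mid) == 20  # cosine peak at the centre
        assert rf[18, 20] < rf[20, 20]  # envelope decays along y too
        np.testing.assert_allclose(
            rf[19, 18:23] / rf[20, 18:23],
            np.full(5, rf[19, 20] / rf[20, 20]), rtol=1e-10,
        )

    def test_bad_eye_rejected(self):
        spec = NeuronSpec.build(0.0, 0.2, 0.0, 0.0, 0)
        with pytest.raises(ValueError):
            sp.gabor_rf(spec, "cyclopean", (41, 41))


class TestEmpiricalPeak:
    """The cancellation contract: every unit's empirical preferred disparity
    is (dx_enc, 0), exactly on the integer grid for zero phase disparity
    and for the narrowband high-frequency channel; the residual of the
    narrowband approximation stays within one pixel at f = 0.0707."""

    DISPS = np.array([(dx, dy) for dx in range(-8, 9) for dy in range(-4, 5)])

    def test_symmetric_unit_peaks_at_origin(self, small_grid):
        u = small_grid.unit_index(0.0, 0.2, 0.0, 0)
        pk = sp.empirical_peak(small_grid, u, n_images=40, shape=(61, 61),
                               disparities=self.DISPS, seed=1)
        assert pk == (0, 0)

    @pytest.mark.parametrize("theta,f,dphi,dx_enc", [
        (90.0, 0.2, np.pi / 2, 4),    # validates the cancellation sign:
        (0.0, 0.2, -np.pi / 2, -3),   # a flipped sign would displace the
        (-30.0, 0.2, np.pi / 2, 0),   # peak by ~2 px along (cos t, sin t)
        (90.0, 0.0707, 0.0, 4),
    ])
    def test_peak_at_preferred_horizontal_disparity(
        self, small_grid, theta, f, dphi, dx_enc
    ):
        u = small_grid.unit_index(theta, f, dphi, dx_enc)
        pk = sp.empirical_peak(small_grid, u, n_images=60, shape=(61, 61),
                               disparities=self.DISPS, seed=2)
        assert pk == (dx_enc, 0)

    def test_low_frequency_residual_within_one_pixel(self, small_grid):
        # the narrowband cancellation leaves a sub-pixel pull toward the
        # position disparity; at f = 0.0707, |dphi| = pi/2 it can round to
        # one pixel on the grid but no further
        u = small_grid.unit_index(90.0, 0.0707, np.pi / 2, 2)
        dx, dy = sp.empirical_peak(
            small_grid, u, n_images=60, shape=(61, 61),
            disparities=self.DISPS, seed=3,
        )
        # dy tests the cancellation; dx lies on the elongated (flat) axis
        # of this horizontal unit, where the sampled argmax wobbles
        assert abs(dy) <= 1 and abs(dx - 2) <= 1


def test_oblique_unit_slices_peak_off_zero(small_grid):
    """An oblique unit probed at non-optimal horizontal disparities responds
    best to non-zero vertical disparities, with opposite signs on the two
    sides of the optimum (the tuning surface is elongated along the
    preferred orientation)."""
    u = small_grid.unit_index(-30.0, 0.0707, 0.0, 0)
    dys = np.arange(-5, 6)
    surf = {}
    for dx in (-3, 3):
        disp = np.array([(dx, dy) for dy in dys])
        _, c = sp.unit_tuning_surface(
            small_grid, u, n_images=200, disparities=disp,
            shape=(61, 61), seed=4,
        )
        surf[dx] = dys[int(np.argmax(c))]
    assert surf[-3] != 0 and surf[3] != 0
    assert np.sign(surf[-3]) == -np.sign(surf[3])
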