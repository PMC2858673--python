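"""Energy-model encoder: monocular drives, binocular correlation, spiking."""

import numpy as np
import pytest

import stereopop as sp
from stereopop.population import NeuronSpec, gabor_rf
from stereopop.stimuli import Stereogram


def _matched_units(grid, dx):
    m = grid.complex_units
    return ((m.dphi == 0) & (m.dx_enc == dx)).to_numpy()


class TestBinocularCorrelation:
    @pytest.mark.parametrize("dx,seed", [(4, 1), (-3, 2), (0, 3), (2, 11)])
    def test_matched_units_reach_exactly_one(self, small_encoder, dx, seed):
        # C = 1 for any correlated image whose disparity equals the unit's
        # interocular RF transformation — an identity, not a statistical fact
        sg = sp.generate_stereogram(61, 61, dx, 0, "correlated", seed=seed)
        c = small_encoder.encode(sg).values
        sel = _matched_units(small_encoder.grid, dx)
        np.testing.assert_allclose(c[sel], 1.0, atol=1e-6)

    def test_anticorrelated_twin_reaches_minus_one(self, small_encoder):
        sg = sp.generate_stereogram(61, 61, -3, 0, "anticorrelated", seed=2)
        c = small_encoder.encode(sg).values
        sel = _matched_units(small_encoder.grid, -3)
        np.testing.assert_allclose(c[sel], -1.0, atol=1e-6)

    def test_anticorrelation_antisymmetry_exact(self, small_encoder):
        # same noise stream: C flips sign unit-by-unit (B flips, M fixed)
        a = sp.generate_stereogram(61, 61, 2, -1, "correlated", seed=9)
        b = sp.generate_stereogram(61, 61, 2, -1, "anticorrelated", seed=9)
        ca = small_encoder.encode(a).values
        cb = small_encoder.encode(b).values
        np.testing.assert_allclose(cb, -ca, atol=1e-12)

    def test_bounded_by_one(self, small_encoder):
        left, right = sp.generate_batch(20, 61, 61, 3, 2, "correlated", 21)
        c = small_encoder.correlations_batch(left, right)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)

    def test_contrast_scaling_invariance(self, small_encoder):
        sg = sp.generate_stereogram(61, 61, 1, 1, "correlated", seed=5)
        c1 = small_encoder.correlations_batch(sg.left, sg.right)
        c2 = small_encoder.correlations_batch(7.3 * sg.left, 7.3 * sg.right)
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_blank_stimulus_gives_neutral_zero(self, small_encoder):
        z = np.zeros((61, 61))
        c = small_encoder.correlations_batch(z, z)
        np.testing.assert_array_equal(c, 0.0)

    def test_decorrelation_at_large_vertical_disparity(self, small_encoder):
        # f = 0.2 units (sigma = 1.25 px): a vertical disparity of -8 px
        # decorrelates the two eyes' receptive-field contents entirely
        left, right = sp.generate_batch(150, 61, 61, -2, -8, "correlated", 31)
        c = small_encoder.correlations_batch(left, right)
        f02 = (small_encoder.grid.complex_units.f == 0.2).to_numpy()
        vals = c[:, f02].mean(axis=1)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-3


class TestMonocularResponses:
    def test_fast_path_agrees_with_direct_inner_products(self, small_grid,
                                                         small_encoder):
        sg = sp.generate_stereogram(61, 61, -2, 2, "correlated", seed=7)
        vl_f, vr_f = small_encoder.monocular_responses(sg)
        vl_d, vr_d = sp.monocular_responses_direct(small_grid, sg)
        scale = np.abs(vl_d).max()
        np.testing.assert_allclose(vl_f, vl_d, atol=1e-8 * scale)
        np.testing.assert_allclose(vr_f, vr_d, atol=1e-8 * scale)

    def test_blank_image_zero_drive(self, small_encoder):
        z = np.zeros((61, 61))
        sg = Stereogram(z, z, 0, 0, "correlated")
        vl, vr = small_encoder.monocular_responses(sg)
        np.testing.assert_array_equal(vl, 0.0)
        np.testing.assert_array_equal(vr, 0.0)

    def test_rf_as_stimulus_gives_squared_norm(self, small_encoder):
        # Cauchy-Schwarz equality case: the image IS the receptive field
        spec = small_encoder.grid.simple_cells[40]
        i = 40
        rf = gabor_rf(spec, "left", (61, 61))
        sg = Stereogram(rf, np.zeros_like(rf), 0, 0, "correlated")
        vl, _ = small_encoder.monocular_responses(sg)
        assert vl[i] == pytest.approx(np.sum(rf**2), rel=1e-10)
        assert vl[i] > 0


def test_two_phase_quadrature_equals_many_phases():
    """The (0, pi/2) phase pair gives the same complex-cell C as pooling
    many uniformly spaced phases (the standard quadrature shortcut)."""
    sg = sp.generate_stereogram(41, 41, 2, 1, "correlated", seed=13)

    def c_with_phases(phases, theta=30.0, f=0.15, dphi=np.pi / 4, dx_enc=2):
        b = m = 0.0
        for phi in phases:
            spec = NeuronSpec.build(theta, f, phi, dphi, dx_enc)
            vl = np.sum(gabor_rf(spec, "left", (41, 41)) * sg.left)
            vr = np.sum(gabor_rf(spec, "right", (41, 41)) * sg.right)
            b += 2 * vl * vr
            m += vl**2 + vr**2
        return b / m

    c2 = c_with_phases([0.0, np.pi / 2])
    c8 = c_with_phases(np.arange(8) * np.pi / 8)
    assert c8 == pytest.approx(c2, abs=1e-12)


class TestSpiking:
    def test_mean_spikes_maps_correlation_range(self):
        rv = sp.ResponseVector(np.array([-1.0, 0.0, 1.0]), "correlation")
        m = sp.mean_spikes(rv, 1.0)
        assert m.kind == "mean_spikes"
        np.testing.assert_array_equal(m.values, [0.0, 1.0, 2.0])

    def test_perfectly_anticorrelated_unit_never_spikes(self):
        rv = sp.ResponseVector(np.full(500, -1.0), "correlation")
        counts = sp.spike_counts(rv, 1.0, rng=0)
        assert counts.kind == "spike_counts"
        np.testing.assert_array_equal(counts.values, 0)

    def test_matched_unit_mean_two(self):
        rv = sp.ResponseVector(np.full(20000, 1.0), "correlation")
        counts = sp.spike_counts(rv, 1.0, rng=1)
        m = counts.values.mean()
        assert m == pytest.approx(2.0, abs=3 * np.sqrt(2 / 20000))

    def test_deterministic_given_seed(self):
        rv = sp.ResponseVector(np.zeros(100), "correlation")
        a = sp.spike_counts(rv, 1.0, rng=42).values
        b = sp.spike_counts(rv, 1.0, rng=42).values
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sp.mean_spikes(sp.ResponseVector(np.zeros(3), "correlation"), 0.0)
        with pytest.raises(ValueError):
            sp.mean_spikes(sp.ResponseVector(np.zeros(3), "spike_counts"))
        with pytest.raises(ValueError):
            sp.ResponseVector(np.zeros(3), "firing_rate")
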