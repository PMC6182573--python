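import numpy as np
import pytest

from eicon.core_spectra import EpochedSignals, center_epochs, cross_spectrum, epoch_fft
from eicon.mixing_forward import (
    MixingCoeffs,
    kns_rois,
    mix_two_sensors,
    project_with_background,
    snr_mix,
    synth_layout,
)
from eicon.mixing_forward import SensorLayout
from eicon.simulators import BandlimitedSpec, simulate_bandlimited_pair


class TestMixTwoSensors:
    def test_identity_mixing_passes_x_through(self, rng):
        x = rng.normal(size=(3, 1, 32))
        src = EpochedSignals(np.concatenate([x, np.zeros_like(x)], axis=1), 250.0)
        c = MixingCoeffs(a1=1.0, b1=0.0, a2=0.0, b2=1.0, sigma_u=0.0, sigma_v=0.0)
        mixed = mix_two_sensors(src, c)
        np.testing.assert_array_equal(mixed.data[:, 0], x[:, 0])
        np.testing.assert_array_equal(mixed.data[:, 1], 0.0)

    def test_default_determinant(self):
        assert MixingCoeffs().determinant == pytest.approx(0.3125)

    def test_zero_determinant_warns(self):
        with pytest.warns(UserWarning, match="determinant"):
            MixingCoeffs(a1=1.0, b1=1.0, a2=1.0, b2=1.0)

    def test_wrong_channel_count_rejected(self, rng):
        src = EpochedSignals(rng.normal(size=(2, 3, 16)), 250.0)
        with pytest.raises(ValueError):
            mix_two_sensors(src, MixingCoeffs())


class TestImaginaryPartScaling:
    def test_noise_free_identity(self):
        # Im{S_uv} = (a1 b2 - a2 b1) Im{S_xy}, exactly, per trial
        spec = BandlimitedSpec(delay=4, beta=1.0, a1=1.0, b1=0.0, a2=0.0, b2=1.0)
        src = simulate_bandlimited_pair(spec, 20, 250, seed=3)
        coeffs = MixingCoeffs(sigma_u=0.0, sigma_v=0.0)
        mixed = mix_two_sensors(src, coeffs)
        s_xy = cross_spectrum(epoch_fft(center_epochs(src)), 0, 1)
        s_uv = cross_spectrum(epoch_fft(center_epochs(mixed)), 0, 1)
        np.testing.assert_allclose(
            s_uv.s_uv.imag, coeffs.determinant * s_xy.s_uv.imag, atol=1e-12
        )

    def test_with_noise_at_large_n(self):
        spec = BandlimitedSpec(delay=4, beta=1.0, a1=1.0, b1=0.0, a2=0.0, b2=1.0)
        src = simulate_bandlimited_pair(spec, 1000, 128, seed=4)
        coeffs = MixingCoeffs(sigma_u=0.002, sigma_v=0.002)
        mixed = mix_two_sensors(src, coeffs, seed=5)
        s_xy = cross_spectrum(epoch_fft(center_epochs(src)), 0, 1)
        s_uv = cross_spectrum(epoch_fft(center_epochs(mixed)), 0, 1)
        scale = np.abs(s_xy.s_uv.imag).max()
        err = np.abs(s_uv.s_uv.imag - coeffs.determinant * s_xy.s_uv.imag)
        assert err.max() < 5 * scale / np.sqrt(1000)

    def test_zero_determinant_kills_imaginary_part(self):
        spec = BandlimitedSpec(delay=4, beta=1.0, a1=1.0, b1=0.0, a2=0.0, b2=1.0)
        src = simulate_bandlimited_pair(spec, 20, 250, seed=6)
        with pytest.warns(UserWarning):
            coeffs = MixingCoeffs(a1=0.5, b1=0.5, a2=0.5, b2=0.5,
                                  sigma_u=0.0, sigma_v=0.0)
        mixed = mix_two_sensors(src, coeffs)
        s_uv = cross_spectrum(epoch_fft(center_epochs(mixed)), 0, 1)
        np.testing.assert_allclose(s_uv.s_uv.imag, 0.0, atol=1e-12)


class TestSynthLayout:
    def test_default_sensor_count_and_geometry(self):
        layout, gain = synth_layout(n_sensors=102, n_background=50, roi_positions=3,
                                    seed=0)
        assert layout.n_sensors == 102
        assert gain.gains.shape == (102, 53)
        np.testing.assert_allclose(
            np.linalg.norm(gain.gains, axis=0), 1.0, atol=1e-12
        )

    def test_gain_ordering_equals_distance_ordering(self):
        layout, gain = synth_layout(n_sensors=40, n_background=20, roi_positions=4,
                                    seed=1)
        src = np.concatenate([layout.roi_pos, layout.background_pos])
        for q in range(src.shape[0]):
            d = np.linalg.norm(layout.sensor_pos - src[q], axis=1)
            g = gain.gains[:, q]
            np.testing.assert_array_equal(np.argsort(d), np.argsort(-g))

    def test_center_source_strongest_at_nearest_sensor(self):
        layout, gain = synth_layout(
            n_sensors=30, n_background=5,
            roi_positions=np.array([[0.0, 0.0, 0.75]]), seed=2,
        )
        d = np.linalg.norm(layout.sensor_pos - layout.roi_pos[0], axis=1)
        assert np.argmax(gain.gains[:, 0]) == np.argmin(d)

    def test_roi_outside_shell_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            synth_layout(n_sensors=10, n_background=5,
                         roi_positions=np.array([[0.0, 0.0, 1.5]]), seed=0)


class TestProjection:
    def _rois(self, rng, n_trials=4, n_rois=2, n_samples=50):
        return EpochedSignals(rng.normal(size=(n_trials, n_rois, n_samples)), 250.0)

    def test_alpha_beta_validated(self, rng):
        _, gain = synth_layout(n_sensors=12, n_background=8, roi_positions=2, seed=3)
        rois = self._rois(rng)
        with pytest.raises(ValueError):
            project_with_background(rois, gain, alpha=1.5)
        with pytest.raises(ValueError):
            project_with_background(rois, gain, alpha=0.5, beta=-0.1)

    def test_noise_free_limit_is_pure_projection(self, rng):
        _, gain = synth_layout(n_sensors=12, n_background=8, roi_positions=2, seed=4)
        rois = self._rois(rng)
        out = project_with_background(rois, gain, alpha=1.0, beta=1.0, seed=0)
        expected = np.einsum("sr,nrt->nst", gain.roi_gains, rois.data)
        expected /= np.linalg.norm(expected, axis=(1, 2), keepdims=True)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_unit_norm_when_measurement_step_skipped(self, rng):
        _, gain = synth_layout(n_sensors=12, n_background=8, roi_positions=2, seed=5)
        out = project_with_background(self._rois(rng), gain, alpha=0.5, beta=None,
                                      seed=1)
        np.testing.assert_allclose(
            np.linalg.norm(out.data, axis=(1, 2)), 1.0, atol=1e-12
        )

    def test_snr_mix_norm_of_independent_components(self, rng):
        # ||alpha A + (1-alpha) B|| ~ sqrt(alpha^2 + (1-alpha)^2) for
        # independent unit-norm terms (Monte-Carlo, 2% tolerance)
        alpha = 0.3
        norms = []
        for _ in range(200):
            a = rng.standard_normal((1, 4, 100))
            b = rng.standard_normal((1, 4, 100))
            norms.append(np.linalg.norm(snr_mix(a, b, alpha)))
        expected = np.hypot(alpha, 1 - alpha)
        assert abs(np.mean(norms) - expected) < 0.02 * expected


class TestKNS:
    def test_k_default_and_bounds(self):
        layout, _ = synth_layout(n_sensors=20, n_background=5, roi_positions=2, seed=6)
        rois = kns_rois(layout, 6)
        assert rois.k == 6
        assert all(len(s) == 6 for s in rois.sensors)
        with pytest.raises(ValueError):
            kns_rois(layout, 21)

    def test_k_equals_all_sensors(self):
        layout, _ = synth_layout(n_sensors=8, n_background=5, roi_positions=2, seed=7)
        with pytest.warns(UserWarning, match="overlap"):
            rois = kns_rois(layout, 8)
        assert all(set(s) == set(range(8)) for s in rois.sensors)

    def test_toy_square_hand_computed(self):
        sensors = np.array(
            [[0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0], [1, 1, 0.0]]
        )
        layout = SensorLayout(
            sensor_pos=sensors,
            roi_pos=np.array([[0.1, 0.0, 0.0]]),
            background_pos=np.zeros((1, 3)),
        )
        rois = kns_rois(layout, 2)
        assert rois.sensors[0] == (0, 1)
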