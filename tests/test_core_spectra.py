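import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eicon.core_spectra import (
    DegenerateBinWarning,
    EpochedSignals,
    SpectralEnsemble,
    center_epochs,
    complex_coherence,
    cross_spectrum,
    epoch_fft,
)


def _epochs(data, fs=250.0):
    return EpochedSignals(data=np.asarray(data, dtype=float), fs=fs)


class TestEpochedSignals:
    def test_rejects_non_finite_with_location(self):
        data = np.zeros((2, 2, 4))
        data[1, 0, 2] = np.nan
        with pytest.raises(ValueError, match="trial 1, channel 0"):
            _epochs(data)

    @pytest.mark.parametrize(
        "shape", [(0, 2, 4), (2, 2, 1)], ids=["no-trials", "one-sample"]
    )
    def test_rejects_degenerate_shapes(self, shape):
        with pytest.raises(ValueError):
            _epochs(np.zeros(shape))

    def test_channel_lookup(self):
        x = EpochedSignals(np.zeros((1, 2, 4)), 100.0, channel_ids=("u", "v"))
        assert x.channel_index("v") == 1
        with pytest.raises(KeyError):
            x.channel_index("w")


class TestCentering:
    def test_constant_channel_becomes_zero(self):
        x = _epochs(np.full((2, 1, 8), 5.0))
        assert np.all(center_epochs(x).data == 0.0)

    def test_hand_computed_two_trials(self):
        x = _epochs([[[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]]])
        expected = np.array([[[-1.0, 0.0, 1.0]], [[-1.0, 0.0, 1.0]]])
        np.testing.assert_allclose(center_epochs(x).data, expected)

    def test_idempotent_on_zero_mean_sine(self):
        t = np.arange(100) / 100.0
        x = _epochs(np.sin(2 * np.pi * 5 * t)[None, None, :], fs=100.0)
        np.testing.assert_allclose(center_epochs(x).data, x.data, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mean_removed_for_random_epochs(self, seed):
        rng = np.random.default_rng(seed)
        x = _epochs(rng.normal(3.0, 2.0, size=(3, 2, 32)))
        c = center_epochs(x).data
        assert np.abs(c.mean(axis=2)).max() <= 1e-12 * max(c.std(), 1.0)


class TestEpochFFT:
    def test_paper_grid_one_second_at_250hz(self):
        spec = epoch_fft(_epochs(np.random.default_rng(0).normal(size=(1, 1, 250))))
        assert spec.n_freqs == 126
        np.testing.assert_allclose(spec.freqs, np.arange(126.0))

    def test_pure_cosine_concentrates_in_one_bin(self):
        t = np.arange(250) / 250.0
        spec = epoch_fft(_epochs(np.cos(2 * np.pi * 30 * t)[None, None, :]))
        power = np.abs(spec.coeffs[0, 0]) ** 2
        assert power[30] / power.sum() >= 1.0 - 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([64, 125, 250]))
    def test_parseval(self, seed, nt):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(1, 1, nt))
        spec = epoch_fft(_epochs(x, fs=float(nt)))
        weights = np.full(spec.n_freqs, 2.0)
        weights[0] = 1.0
        if nt % 2 == 0:
            weights[-1] = 1.0
        freq_energy = (weights * np.abs(spec.coeffs[0, 0]) ** 2).sum() / nt
        time_energy = (x**2).sum()
        np.testing.assert_allclose(freq_energy, time_energy, rtol=1e-9)


class TestCrossSpectrum:
    def test_self_pair_is_real_auto_spectrum(self, rng):
        spec = epoch_fft(_epochs(rng.normal(size=(5, 2, 64))))
        cs = cross_spectrum(spec, 0, 0)
        np.testing.assert_allclose(cs.s_uv.imag, 0.0, atol=1e-12)
        np.testing.assert_allclose(cs.s_uv.real, cs.s_uu, rtol=1e-12)

    def test_two_trial_brute_force(self):
        coeffs = np.array(
            [
                [[1 + 2j, -1j, 0.5], [2 - 1j, 3j, 1 + 1j]],
                [[0.5j, 2 + 2j, -1], [1, -2j, 0.25 - 1j]],
            ]
        )
        spec = SpectralEnsemble(coeffs, freqs=np.arange(3.0), fs=6.0)
        cs = cross_spectrum(spec, 0, 1)
        expected = (
            coeffs[0, 0] * coeffs[0, 1].conj() + coeffs[1, 0] * coeffs[1, 1].conj()
        ) / 2.0
        np.testing.assert_allclose(cs.s_uv, expected, atol=1e-12)

    def test_sign_linearity(self, rng):
        data = rng.normal(size=(4, 1, 32))
        x = _epochs(np.concatenate([data, -data], axis=1))
        spec = epoch_fft(x)
        cs = cross_spectrum(spec, 0, 1)
        np.testing.assert_allclose(cs.s_uv, -cs.s_uu, rtol=1e-12, atol=1e-12)

    def test_hermitian_symmetry(self, rng):
        spec = epoch_fft(_epochs(rng.normal(size=(6, 2, 64))))
        ab = cross_spectrum(spec, 0, 1)
        ba = cross_spectrum(spec, 1, 0)
        np.testing.assert_allclose(ab.s_uv, ba.s_uv.conj(), rtol=1e-12, atol=1e-14)

    def test_unknown_channel(self, rng):
        spec = epoch_fft(_epochs(rng.normal(size=(2, 2, 16))))
        with pytest.raises(KeyError):
            cross_spectrum(spec, 0, "nope")


class TestComplexCoherence:
    def test_identical_channels_give_unity(self, rng):
        data = rng.normal(size=(5, 1, 64))
        spec = epoch_fft(center_epochs(_epochs(np.repeat(data, 2, axis=1))))
        c = complex_coherence(cross_spectrum(spec, 0, 1))
        np.testing.assert_allclose(c[1:], 1.0 + 0j, atol=1e-10)

    def test_zero_power_bin_yields_zero_with_warning(self, rng):
        data = rng.normal(size=(4, 2, 64))
        data[:, 1, :] = 0.0  # second channel carries no power at all
        spec = epoch_fft(_epochs(data))
        with pytest.warns(DegenerateBinWarning):
            c = complex_coherence(cross_spectrum(spec, 0, 1))
        np.testing.assert_array_equal(c, 0.0)

    def test_single_trial_degenerates_to_unit_magnitude(self, rng):
        spec = epoch_fft(_epochs(rng.normal(size=(1, 2, 64))))
        c = complex_coherence(cross_spectrum(spec, 0, 1))
        np.testing.assert_allclose(np.abs(c), 1.0, atol=1e-9)

    def test_magnitude_bounded(self, rng):
        spec = epoch_fft(_epochs(rng.normal(size=(8, 2, 128))))
        c = complex_coherence(cross_spectrum(spec, 0, 1))
        assert np.abs(c).max() <= 1.0 + 1e-9

    def test_scale_invariance(self, rng):
        data = rng.normal(size=(6, 2, 64))
        scaled = data.copy()
        scaled[:, 0, :] *= 37.5
        c1 = complex_coherence(cross_spectrum(epoch_fft(_epochs(data)), 0, 1))
        c2 = complex_coherence(cross_spectrum(epoch_fft(_epochs(scaled)), 0, 1))
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_null_coherence_bias_matches_permutation_oracle(self):
        # mean |C| of independent white noise ~ sqrt(pi)/2 / sqrt(N)
        rng = np.random.default_rng(99)
        n = 100
        spec = epoch_fft(_epochs(rng.normal(size=(n, 2, 64))))
        c = complex_coherence(cross_spectrum(spec, 0, 1))
        observed = np.abs(c[1:]).mean()
        # permutation oracle: re-pair trials at random, same statistic
        perm_vals = []
        for _ in range(50):
            perm = rng.permutation(n)
            u = spec.coeffs[:, 0, 1:]
            v = spec.coeffs[perm, 1, 1:]
            s_uv = (u * v.conj()).mean(axis=0)
            s_uu = (np.abs(u) ** 2).mean(axis=0)
            s_vv = (np.abs(v) ** 2).mean(axis=0)
            perm_vals.append(np.abs(s_uv / np.sqrt(s_uu * s_vv)).mean())
        assert abs(observed - np.mean(perm_vals)) < 3 * np.std(perm_vals)
        assert observed < 3.0 / np.sqrt(n)
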