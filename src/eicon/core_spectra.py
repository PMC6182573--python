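"""Epoch-wise Fourier analysis and cross-spectral / coherence estimation.

Every connectivity measure in this package starts from the same primitive: a
set of per-epoch one-sided Fourier coefficients on a common frequency grid.
Epochs (trials) are treated as independent realizations of the same process,
and ensemble averages over epochs play the role of the expectation operator
in the estimator formulas.

Conventions
-----------
* No taper is applied before the FFT by default (a Hann taper is available
  via ``epoch_fft(..., taper="hann")`` but defaults off).
* One-sided spectrum; the DC bin and the Nyquist bin are included. After
  per-epoch centering the DC coefficient is numerically zero.
* No zero padding: the frequency resolution is exactly ``fs / n_samples``
  (1 Hz for 1 s epochs sampled at 250 Hz).
* Frequency bins where an auto-spectrum vanishes yield coherence 0 (with a
  warning) instead of propagating NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EpochedSignals",
    "SpectralEnsemble",
    "CrossSpectrum",
    "center_epochs",
    "epoch_fft",
    "cross_spectrum",
    "complex_coherence",
    "DegenerateBinWarning",
]


class DegenerateBinWarning(UserWarning):
    """Raised when a 0/0-type convention (coherence at a zero-power bin,

    wPLI with an all-zero imaginary cross-spectrum, ...) is applied."""


def _as_channel_ids(ids, n_channels: int) -> tuple:
    if ids is None:
        return tuple(f"ch{i}" for i in range(n_channels))
    ids = tuple(str(c) for c in ids)
    if len(ids) != n_channels:
        raise ValueError(
            f"channel_ids has {len(ids)} entries for {n_channels} channels"
        )
    if len(set(ids)) != len(ids):
        raise ValueError("channel_ids must be unique")
    return ids


@dataclass(frozen=True)
class EpochedSignals:
    """Multi-trial, multi-channel time series.

    Parameters
    ----------
    data
        Real array of shape ``(n_trials, n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_ids
        Optional channel labels; defaults to ``ch0, ch1, ...``.
    """

    data: np.ndarray
    fs: float
    channel_ids: tuple = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(
                f"data must be (n_trials, n_channels, n_samples), got ndim={data.ndim}"
            )
        if data.shape[0] < 1 or data.shape[2] < 2:
            raise ValueError(
                f"need n_trials >= 1 and n_samples >= 2, got shape {data.shape}"
            )
        if not float(self.fs) > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(data)):
            n, c, _ = np.unravel_index(
                np.argmin(np.isfinite(data)), data.shape
            )
            raise ValueError(
                f"non-finite sample in trial {n}, channel {c}"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(
            self, "channel_ids", _as_channel_ids(self.channel_ids, data.shape[1])
        )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, channel) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_ids.index(str(channel))
        except ValueError:
            raise KeyError(f"unknown channel id {channel!r}") from None


def center_epochs(x: EpochedSignals) -> EpochedSignals:
    """Remove the per-trial, per-channel mean (the only detrending applied)."""
    centered = x.data - x.data.mean(axis=2, keepdims=True)
    return replace(x, data=centered)


@dataclass(frozen=True)
class SpectralEnsemble:
    """Per-trial one-sided Fourier coefficients on a fixed frequency grid."""

    coeffs: np.ndarray  # complex, (n_trials, n_channels, n_freqs)
    freqs: np.ndarray  # Hz, strictly increasing, uniform
    fs: float
    channel_ids: tuple = None

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=complex)
        freqs = np.asarray(self.freqs, dtype=float)
        if coeffs.ndim != 3:
            raise ValueError("coeffs must be (n_trials, n_channels, n_freqs)")
        if freqs.ndim != 1 or freqs.size != coeffs.shape[2]:
            raise ValueError("freqs must match the last coeffs axis")
        if freqs.size >= 2:
            steps = np.diff(freqs)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("freqs must be strictly increasing and uniform")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("non-finite Fourier coefficient")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(
            self, "channel_ids", _as_channel_ids(self.channel_ids, coeffs.shape[1])
        )

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_freqs(self) -> int:
        return self.coeffs.shape[2]

    def channel_index(self, channel) -> int:
        return EpochedSignals.channel_index(self, channel)


def epoch_fft(x: EpochedSignals, taper: str | None = None) -> SpectralEnsemble:
    """One-sided DFT of every trial and channel.

    ``taper`` may be ``"hann"``; the default (``None``) is a rectangular
    window, matching the plain per-epoch Fourier estimator.
    """
    if x.n_samples < 2:
        raise ValueError("need at least 2 samples per epoch")
    data = x.data
    if taper is not None:
        if taper != "hann":
            raise ValueError(f"unknown taper {taper!r}")
        data = data * np.hanning(x.n_samples)
    coeffs = np.fft.rfft(data, axis=2)
    freqs = np.fft.rfftfreq(x.n_samples, d=1.0 / x.fs)
    return SpectralEnsemble(
        coeffs=coeffs, freqs=freqs, fs=x.fs, channel_ids=x.channel_ids
    )


@dataclass(frozen=True)
class CrossSpectrum:
    """Trial-averaged cross- and auto-spectra for one channel pair."""

    s_uv: np.ndarray  # complex (n_freqs,)
    s_uu: np.ndarray  # real, nonnegative
    s_vv: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        for name in ("s_uu", "s_vv"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < -1e-12 * max(1.0, arr.max(initial=0.0))):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, np.maximum(arr, 0.0))
        object.__setattr__(self, "s_uv", np.asarray(self.s_uv, dtype=complex))
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))


def cross_spectrum(spec: SpectralEnsemble, ch_u, ch_v) -> CrossSpectrum:
    """S_uv(f) = (1/N) sum_n U_n(f) V_n(f)*, with the matching auto-spectra."""
    iu = spec.channel_index(ch_u)
    iv = spec.channel_index(ch_v)
    u = spec.coeffs[:, iu, :]
    v = spec.coeffs[:, iv, :]
    s_uv = (u * v.conj()).mean(axis=0)
    s_uu = (u * u.conj()).real.mean(axis=0)
    s_vv = (v * v.conj()).real.mean(axis=0)
    return CrossSpectrum(s_uv=s_uv, s_uu=s_uu, s_vv=s_vv, freqs=spec.freqs)


def complex_coherence(cs: CrossSpectrum) -> np.ndarray:
    """C_uv(f) = S_uv(f) / sqrt(S_uu(f) S_vv(f)); 0 at zero-power bins."""
    denom = np.sqrt(cs.s_uu * cs.s_vv)
    out = np.zeros_like(cs.s_uv)
    ok = denom > 0
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} zero-power bin(s): coherence set to 0 there",
            DegenerateBinWarning,
            stacklevel=2,
        )
    out[ok] = cs.s_uv[ok] / denom[ok]
    return out
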