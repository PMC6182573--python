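"""Frequency-domain functional-connectivity measures.

Nine estimators are implemented, all computed from the same per-epoch
Fourier coefficients (see :mod:`eicon.core_spectra`). Writing U_n(f), V_n(f)
for the coefficients of the two channels in epoch n and E[.] for the average
over epochs:

====== =====================================================================
coh    |C_uv(f)|, C_uv = E[U V*] / sqrt(E[|U|^2] E[|V|^2])
plv    |E[exp(j (phase U - phase V))]|
icoh1  Im{C_uv(f)}                       (imaginary coherence)
icoh2  E[Im{U V*}] / E[|H(Im{U V*})|]    (Hilbert-normalized variant)
pli    |E[sgn Im{U V*}]|                 (phase-lag index, sgn(0) = 0)
wpli   |E[Im{U V*}]| / E[|Im{U V*}|]     (weighted PLI, 0/0 -> 0)
lcoh   Im{C_uv}^2 / (1 - Re{C_uv}^2)     (lagged coherence)
eic1   |H(icoh1)|                        (envelope of imaginary coherence)
eic2   |H(icoh2)|
====== =====================================================================

H is the discrete analytic-signal (Hilbert-transform) operator applied to a
real curve *along the frequency axis*: the envelope of a zero-lag-blind
quantity approximately restores the magnitude information that discarding
the real part removed, which is what makes eic2 sensitive to interactions
whose phase difference sits at 0 or pi where Im{S_uv} vanishes.

Volume conduction (instantaneous mixing of sources into sensors) inflates
coh and plv but leaves Im{S_uv} a pure scaled copy of the source-level
imaginary cross-spectrum, so icoh1/icoh2/pli/wpli/eic2 are robust to it.

The icoh2/eic2 denominator applies H per epoch to Im{U_n V_n*} as a function
of frequency and then averages the envelope magnitudes over epochs
(``icoh2_norm="per-trial"``); averaging first and applying H once is exposed
as ``icoh2_norm="post-average"`` for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import hilbert

from .core_spectra import DegenerateBinWarning, SpectralEnsemble

__all__ = [
    "MEASURES",
    "SIGNED_MEASURES",
    "EnvelopeCurve",
    "FCCurve",
    "hilbert_envelope",
    "measure_curve",
    "fc_all_pairs",
]

#: All supported measure identifiers (lower case).
MEASURES = ("coh", "plv", "icoh1", "icoh2", "pli", "wpli", "lcoh", "eic1", "eic2")

#: Measures that carry a sign (two-sided surrogate thresholds apply).
SIGNED_MEASURES = frozenset({"icoh1", "icoh2"})

#: Allowed envelope overshoot for the bounded eic2 curve (edge effects of the
#: discrete analytic signal; values are reported unclipped).
EIC_OVERSHOOT_TOL = 0.05


def canonical_measure(measure: str) -> str:
    m = str(measure).lower()
    if m not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    return m


# ---------------------------------------------------------------------------
# Hilbert envelope of a real sequence
# ---------------------------------------------------------------------------


def _analytic(z: np.ndarray, axis: int = -1, pad: bool = False) -> np.ndarray:
    """Discrete analytic signal of a real sequence along ``axis``.

    ``pad=True`` mirrors the sequence at both ends before the transform and
    crops afterwards, which damps edge overshoot at the cost of no longer
    being the plain textbook operator. Default off.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[axis]
    if n < 4:
        raise ValueError(f"need a sequence of length >= 4, got {n}")
    if not pad:
        return hilbert(z, axis=axis)
    z = np.moveaxis(z, axis, -1)
    ext = np.concatenate([z[..., ::-1], z, z[..., ::-1]], axis=-1)
    h = hilbert(ext, axis=-1)[..., n : 2 * n]
    return np.moveaxis(h, -1, axis)


def _envelope(z: np.ndarray, axis: int = -1, pad: bool = False) -> np.ndarray:
    return np.abs(_analytic(z, axis=axis, pad=pad))


@dataclass(frozen=True)
class EnvelopeCurve:
    """A real curve, its quadrature component and the analytic envelope."""

    values: np.ndarray
    quadrature: np.ndarray
    envelope: np.ndarray


def hilbert_envelope(z: np.ndarray, pad: bool = False) -> EnvelopeCurve:
    """Analytic-signal envelope of a real sequence.

    The sequence is treated as an ordinary discrete signal; in this package
    it is usually a connectivity curve over the one-sided frequency grid.
    The envelope dominates the input pointwise: ``envelope >= |z|``.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("hilbert_envelope expects a 1-D sequence")
    h = _analytic(z, axis=-1, pad=pad)
    return EnvelopeCurve(values=z, quadrature=h.imag, envelope=np.abs(h))


# ---------------------------------------------------------------------------
# Measure kernel
# ---------------------------------------------------------------------------


def _measure_kernel(
    measure: str,
    cross: np.ndarray,
    ncross: np.ndarray | None,
    s_uu: np.ndarray,
    s_vv: np.ndarray,
    trial_axis: int = 0,
    icoh2_norm: str = "per-trial",
    warn: bool = True,
) -> np.ndarray:
    """Evaluate one measure from per-trial cross terms.

    Parameters
    ----------
    cross
        ``U_n(f) V_n(f)*`` with the epoch axis at ``trial_axis`` and frequency
        on the last axis; leading axes (surrogates, pairs) broadcast through.
    ncross
        The same product of unit-magnitude coefficients (needed for plv only).
    s_uu, s_vv
        Trial-averaged auto-spectra, broadcastable against the output. They
        are invariant under epoch permutation, so surrogate paths reuse them.
    """
    m = measure
    ax = trial_axis

    def _coherence():
        denom = np.sqrt(s_uu * s_vv)
        s_uv = cross.mean(axis=ax)
        out = np.zeros_like(s_uv)
        ok = np.broadcast_to(denom > 0, s_uv.shape)
        np.divide(s_uv, np.broadcast_to(denom, s_uv.shape), out=out, where=ok)
        if warn and not np.all(ok):
            warnings.warn(
                "zero-power bin(s): coherence-based value set to 0 there",
                DegenerateBinWarning,
                stacklevel=3,
            )
        return out

    if m == "coh":
        return np.abs(_coherence())
    if m == "plv":
        if ncross is None:
            raise ValueError("plv needs normalized cross terms")
        return np.abs(ncross.mean(axis=ax))
    if m == "icoh1":
        return _coherence().imag
    if m == "lcoh":
        c = _coherence()
        den = 1.0 - c.real**2
        out = np.zeros(c.shape, dtype=float)
        ok = den > 1e-12
        np.divide(c.imag**2, den, out=out, where=ok)
        if warn and not np.all(ok):
            warnings.warn(
                "lagged-coherence denominator underflow: value set to 0",
                DegenerateBinWarning,
                stacklevel=3,
            )
        return out

    # guard: an exactly real cross term can pick up O(eps)*|cross| imaginary
    # rounding noise in the complex multiply; sgn() and the 0/0 conventions
    # must not react to it
    im = cross.imag.copy()
    im[np.abs(im) <= 1e-12 * np.abs(cross)] = 0.0
    if m == "pli":
        return np.abs(np.sign(im).mean(axis=ax))
    if m == "wpli":
        num = np.abs(im.mean(axis=ax))
        den = np.abs(im).mean(axis=ax)
        out = np.zeros_like(num)
        ok = den > 0
        np.divide(num, den, out=out, where=ok)
        if warn and not np.all(ok):
            warnings.warn(
                "wPLI 0/0 bin(s): value set to 0", DegenerateBinWarning, stacklevel=3
            )
        return out
    if m in ("icoh2", "eic2"):
        num = im.mean(axis=ax)
        if icoh2_norm == "per-trial":
            den = _envelope(im, axis=-1).mean(axis=ax)
        elif icoh2_norm == "post-average":
            den = _envelope(num, axis=-1)
        else:
            raise ValueError(f"unknown icoh2_norm {icoh2_norm!r}")
        out = np.zeros_like(num)
        ok = den > 0
        np.divide(num, den, out=out, where=ok)
        if warn and not np.any(ok):
            warnings.warn(
                "all-zero icoh2 normalization curve: measure set to 0",
                DegenerateBinWarning,
                stacklevel=3,
            )
        if m == "icoh2":
            return out
        return _envelope(out, axis=-1)
    if m == "eic1":
        return _envelope(_coherence().imag, axis=-1)
    raise ValueError(f"unknown measure {measure!r}")


def _pair_inputs(spec: SpectralEnsemble, ch_u, ch_v):
    iu = spec.channel_index(ch_u)
    iv = spec.channel_index(ch_v)
    u = spec.coeffs[:, iu, :]
    v = spec.coeffs[:, iv, :]
    cross = u * v.conj()
    mag_u = np.abs(u)
    mag_v = np.abs(v)
    nu = np.where(mag_u > 0, u / np.where(mag_u > 0, mag_u, 1.0), 0.0)
    nv = np.where(mag_v > 0, v / np.where(mag_v > 0, mag_v, 1.0), 0.0)
    ncross = nu * nv.conj()
    s_uu = (mag_u**2).mean(axis=0)
    s_vv = (mag_v**2).mean(axis=0)
    return cross, ncross, s_uu, s_vv


@dataclass(frozen=True)
class FCCurve:
    """One measure's value per frequency for a single channel pair."""

    measure: str
    values: np.ndarray
    freqs: np.ndarray
    pair: tuple

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        if self.values.shape != self.freqs.shape:
            raise ValueError("values and freqs must have matching shapes")


def measure_curve(
    spec: SpectralEnsemble,
    measure: str,
    ch_u,
    ch_v,
    icoh2_norm: str = "per-trial",
) -> FCCurve:
    """Compute one connectivity measure for one channel pair.

    For the Hilbert-based measures (icoh2, eic1, eic2) at least 4 frequency
    bins are required.
    """
    m = canonical_measure(measure)
    cross, ncross, s_uu, s_vv = _pair_inputs(spec, ch_u, ch_v)
    values = _measure_kernel(
        m, cross, ncross, s_uu, s_vv, trial_axis=0, icoh2_norm=icoh2_norm
    )
    return FCCurve(
        measure=m,
        values=values,
        freqs=spec.freqs,
        pair=(spec.channel_ids[spec.channel_index(ch_u)],
              spec.channel_ids[spec.channel_index(ch_v)]),
    )


def fc_all_pairs(
    spec: SpectralEnsemble, measure: str, icoh2_norm: str = "per-trial"
) -> dict:
    """Measure curves for every unordered channel pair.

    Returns a dict keyed by ``(channel_id_u, channel_id_v)`` with u before v
    in channel order; C channels yield C(C-1)/2 curves.
    """
    if spec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    out = {}
    for iu, iv in combinations(range(spec.n_channels), 2):
        key = (spec.channel_ids[iu], spec.channel_ids[iv])
        out[key] = measure_curve(spec, measure, iu, iv, icoh2_norm=icoh2_norm)
    return out
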