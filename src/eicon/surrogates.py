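"""Surrogate-data significance thresholds for connectivity curves.

The null hypothesis of no epoch-consistent phase relationship is simulated
by shuffling the epoch correspondence between the two channels: for each
surrogate a uniform random permutation re-pairs channel v's epochs with
channel u's, the measure is recomputed, and the extreme (or a chosen
percentile) of the surrogate distribution is taken per frequency bin,
separately. Within-epoch spectra are untouched, so amplitude structure is
preserved while cross-epoch phase consistency is destroyed.

With the default ``percentile=1.0`` the threshold is the per-bin maximum
over surrogates (the classical max-statistic construction); the default
surrogate count is 1000. The identity permutation is not excluded — its
probability is negligible for realistic trial counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_spectra import SpectralEnsemble
from .fc_measures import SIGNED_MEASURES, _measure_kernel, canonical_measure
from .fc_measures import FCCurve

__all__ = [
    "SurrogateThreshold",
    "surrogate_threshold",
    "significant_mask",
    "significant_at",
]


@dataclass(frozen=True)
class SurrogateThreshold:
    """Per-frequency significance cutoffs from epoch-shuffled surrogates."""

    upper: np.ndarray
    lower: np.ndarray  # mirror cutoff; meaningful for signed measures
    freqs: np.ndarray
    measure: str
    n_surrogates: int
    percentile: float
    seed: object = None


def surrogate_threshold(
    spec: SpectralEnsemble,
    ch_u,
    ch_v,
    measure: str,
    n_surrogates: int = 1000,
    percentile: float = 1.0,
    seed=None,
    icoh2_norm: str = "per-trial",
    chunk: int = 128,
) -> SurrogateThreshold:
    """Epoch-shuffling surrogate threshold for one pair and measure.

    Parameters
    ----------
    percentile
        Fraction in (0, 1]; 1.0 keeps the per-bin maximum (minimum for the
        lower branch of signed measures).
    seed
        Anything accepted by :func:`numpy.random.default_rng`; fixing it makes
        the permutation stream, and hence the thresholds, fully deterministic.
    chunk
        Number of surrogates evaluated per vectorized block (memory knob).
    """
    m = canonical_measure(measure)
    if spec.n_trials < 2:
        raise ValueError("need at least 2 trials to shuffle epoch pairing")
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n = spec.n_trials
    iu = spec.channel_index(ch_u)
    iv = spec.channel_index(ch_v)
    u = spec.coeffs[:, iu, :]
    v = spec.coeffs[:, iv, :]
    mag_u = np.abs(u)
    mag_v = np.abs(v)
    nu = np.where(mag_u > 0, u / np.where(mag_u > 0, mag_u, 1.0), 0.0)
    nv = np.where(mag_v > 0, v / np.where(mag_v > 0, mag_v, 1.0), 0.0)
    # Auto-spectra are means over epochs, hence invariant to the shuffling.
    s_uu = (mag_u**2).mean(axis=0)
    s_vv = (mag_v**2).mean(axis=0)

    perms = np.stack([rng.permutation(n) for _ in range(n_surrogates)])
    vals = np.empty((n_surrogates, spec.n_freqs))
    for start in range(0, n_surrogates, chunk):
        blk = perms[start : start + chunk]  # (S, N)
        cross = u[None, :, :] * v[blk].conj()  # (S, N, F)
        ncross = nu[None, :, :] * nv[blk].conj() if m == "plv" else None
        vals[start : start + len(blk)] = _measure_kernel(
            m, cross, ncross, s_uu, s_vv, trial_axis=1,
            icoh2_norm=icoh2_norm, warn=False,
        )
    upper = np.quantile(vals, percentile, axis=0)
    lower = np.quantile(vals, 1.0 - percentile, axis=0)
    return SurrogateThreshold(
        upper=upper,
        lower=lower,
        freqs=spec.freqs,
        measure=m,
        n_surrogates=int(n_surrogates),
        percentile=float(percentile),
        seed=seed,
    )


def significant_mask(curve: FCCurve, thr: SurrogateThreshold) -> np.ndarray:
    """Boolean curve: where the measure escapes the surrogate band.

    For magnitude measures only the upper cutoff applies; for signed
    measures (icoh1, icoh2) a value below the lower cutoff also counts.
    """
    if curve.freqs.shape != thr.freqs.shape or not np.allclose(
        curve.freqs, thr.freqs
    ):
        raise ValueError("curve and threshold frequency grids do not match")
    mask = curve.values > thr.upper
    if curve.measure in SIGNED_MEASURES:
        mask |= curve.values < thr.lower
    return mask


def significant_at(curve: FCCurve, thr: SurrogateThreshold, freq_hz: float) -> bool:
    """Significance at one frequency, linearly interpolated between bins.

    Useful when the frequency of interest (e.g. 15.625 Hz for 1 s epochs at
    250 Hz) falls between grid bins: curve and cutoffs are interpolated to
    ``freq_hz`` before comparing, so a measure whose curve crosses zero at
    the target frequency — imaginary coherence under an exact pi-phase lag —
    is correctly read as non-significant there even when the two flanking
    bins carry opposite-signed significant values.
    """
    if not curve.freqs[0] <= freq_hz <= curve.freqs[-1]:
        raise ValueError(f"{freq_hz} Hz is outside the frequency grid")
    val = float(np.interp(freq_hz, curve.freqs, curve.values))
    upper = float(np.interp(freq_hz, thr.freqs, thr.upper))
    if val > upper:
        return True
    if curve.measure in SIGNED_MEASURES:
        lower = float(np.interp(freq_hz, thr.freqs, thr.lower))
        return val < lower
    return False
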