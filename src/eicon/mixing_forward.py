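"""Sensor-space realization of simulated source activity.

Two levels of forward model are provided:

* **Two-sensor local leadfield** — the minimal mixing model
  u = a1 x + b1 y + eps_u, v = a2 x + b2 y + eps_v. Its key property is that
  Im{S_uv} = (a1 b2 - a2 b1) Im{S_xy}: the imaginary cross-spectrum of the
  sensors is an exactly scaled copy of the sources', so instantaneous mixing
  alone cannot create a spurious imaginary part (it vanishes only when the
  mixing determinant is zero).
* **Synthetic multi-sensor layout** — sensors quasi-uniform on a spherical
  cap, region and background sources inside the cap, and a distance-falloff
  gain matrix g(s, q) = 1 / (d(s, q)^2 + eps0) with unit-norm columns. This
  is a documented synthetic geometry: it preserves the one property the
  nearest-sensor evaluation needs (gain ordering equals distance ordering)
  without any anatomical or dipole-orientation modeling.

Region activity is projected through the gains, blended with projected
white-noise background activity at a signal-to-background ratio alpha, and
finally with independent per-sensor measurement noise at an SNR weight beta,
each blend between per-trial Frobenius-normalized terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_spectra import EpochedSignals

__all__ = [
    "MixingCoeffs",
    "SensorLayout",
    "GainMatrix",
    "SensorROIs",
    "mix_two_sensors",
    "synth_layout",
    "project_with_background",
    "kns_rois",
    "snr_mix",
]


@dataclass(frozen=True)
class MixingCoeffs:
    """Local leadfield gains of the two-sensor model.

    ``sigma_u``/``sigma_v`` are the sensor-noise standard deviations; None
    means 10% of the corresponding noiseless mixed signal's sd.
    """

    a1: float = 0.75
    b1: float = 0.5
    a2: float = 0.5
    b2: float = 0.75
    sigma_u: float | None = None
    sigma_v: float | None = None

    def __post_init__(self):
        vals = (self.a1, self.b1, self.a2, self.b2)
        if not all(np.isfinite(vals)):
            raise ValueError("mixing coefficients must be finite")
        if self.determinant == 0.0:
            warnings.warn(
                "mixing determinant a1*b2 - a2*b1 is zero: the sensor "
                "imaginary cross-spectrum degenerates to 0",
                UserWarning,
                stacklevel=2,
            )

    @property
    def determinant(self) -> float:
        return self.a1 * self.b2 - self.a2 * self.b1


def mix_two_sensors(
    sources: EpochedSignals, coeffs: MixingCoeffs = MixingCoeffs(), seed=None
) -> EpochedSignals:
    """Mix a two-channel source process into two noisy sensors.

    ``sources`` must have exactly two channels (x first, y second); the
    returned epochs carry channels ("u", "v").
    """
    if sources.n_channels != 2:
        raise ValueError(
            f"expected 2 source channels, got {sources.n_channels}"
        )
    rng = np.random.default_rng(seed)
    x = sources.data[:, 0, :]
    y = sources.data[:, 1, :]
    u = coeffs.a1 * x + coeffs.b1 * y
    v = coeffs.a2 * x + coeffs.b2 * y
    sigma_u = coeffs.sigma_u if coeffs.sigma_u is not None else 0.1 * u.std()
    sigma_v = coeffs.sigma_v if coeffs.sigma_v is not None else 0.1 * v.std()
    if sigma_u > 0:
        u = u + rng.normal(0.0, sigma_u, size=u.shape)
    if sigma_v > 0:
        v = v + rng.normal(0.0, sigma_v, size=v.shape)
    return EpochedSignals(
        data=np.stack([u, v], axis=1), fs=sources.fs, channel_ids=("u", "v")
    )


@dataclass(frozen=True)
class SensorLayout:
    """Synthetic sensor cap with region and background source positions."""

    sensor_pos: np.ndarray  # (n_sensors, 3)
    roi_pos: np.ndarray  # (n_rois, 3)
    background_pos: np.ndarray  # (n_background, 3)
    radius: float = 1.0

    def __post_init__(self):
        for name in ("sensor_pos", "roi_pos", "background_pos"):
            object.__setattr__(
                self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            )
        if len(np.unique(self.sensor_pos, axis=0)) != len(self.sensor_pos):
            raise ValueError("sensor positions must be distinct")

    @property
    def n_sensors(self) -> int:
        return self.sensor_pos.shape[0]

    @property
    def n_rois(self) -> int:
        return self.roi_pos.shape[0]


@dataclass(frozen=True)
class GainMatrix:
    """Sensors x (regions + background) gains; columns unit-normalized."""

    gains: np.ndarray
    n_rois: int

    def __post_init__(self):
        g = np.asarray(self.gains, dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError("gains must be finite")
        if np.any(np.linalg.norm(g, axis=0) == 0):
            raise ValueError("every gain column must be nonzero")
        object.__setattr__(self, "gains", g)

    @property
    def roi_gains(self) -> np.ndarray:
        return self.gains[:, : self.n_rois]

    @property
    def background_gains(self) -> np.ndarray:
        return self.gains[:, self.n_rois :]


def _cap_points(n: int, radius: float, zmin_frac: float) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice on a spherical cap z >= zmin_frac*r."""
    i = np.arange(n)
    z = zmin_frac + (1.0 - zmin_frac) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return radius * pts


def default_roi_positions(n_rois: int, radius: float = 1.0) -> np.ndarray:
    """Well-separated region seeds: a ring at 0.75 r, polar angle 40 degrees."""
    theta = np.deg2rad(40.0)
    az = 2.0 * np.pi * np.arange(n_rois) / max(n_rois, 1)
    r = 0.75 * radius
    return np.stack(
        [
            r * np.sin(theta) * np.cos(az),
            r * np.sin(theta) * np.sin(az),
            np.full(n_rois, r * np.cos(theta)),
        ],
        axis=1,
    )


def synth_layout(
    n_sensors: int = 102,
    n_background: int = 500,
    roi_positions=3,
    seed=None,
    radius: float = 1.0,
) -> tuple[SensorLayout, GainMatrix]:
    """Synthetic cap layout plus distance-falloff gain matrix.

    ``roi_positions`` is either an integer (that many default ring
    positions) or an (n_rois, 3) array of positions strictly inside the
    sensor shell. Background sources are drawn uniformly in the cap volume
    at radii 0.4–0.85 r. Gains are 1 / (d^2 + 0.02 r^2), columns scaled to
    unit norm so the signal-to-background weight alone sets their balance.
    """
    if n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    rng = np.random.default_rng(seed)
    sensors = _cap_points(n_sensors, radius, zmin_frac=0.25)
    if isinstance(roi_positions, (int, np.integer)):
        rois = default_roi_positions(int(roi_positions), radius)
    else:
        rois = np.atleast_2d(np.asarray(roi_positions, dtype=float))
    if np.any(np.linalg.norm(rois, axis=1) >= radius):
        raise ValueError("region positions must lie strictly inside the sensor shell")

    zmin = 0.25
    costheta = rng.uniform(zmin, 1.0, size=n_background)
    sintheta = np.sqrt(1.0 - costheta**2)
    az = rng.uniform(0.0, 2.0 * np.pi, size=n_background)
    rad = radius * rng.uniform(0.4, 0.85, size=n_background)
    bg = np.stack(
        [rad * sintheta * np.cos(az), rad * sintheta * np.sin(az), rad * costheta],
        axis=1,
    )

    layout = SensorLayout(
        sensor_pos=sensors, roi_pos=rois, background_pos=bg, radius=radius
    )
    src = np.concatenate([rois, bg], axis=0)
    d2 = ((sensors[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    gains = 1.0 / (d2 + 0.02 * radius**2)
    gains = gains / np.linalg.norm(gains, axis=0, keepdims=True)
    return layout, GainMatrix(gains=gains, n_rois=rois.shape[0])


def snr_mix(signal: np.ndarray, noise: np.ndarray, weight: float) -> np.ndarray:
    """weight * S/||S|| + (1 - weight) * N/||N||, Frobenius norms per trial.

    Both inputs are (n_trials, n_sensors, n_samples); the norm is taken over
    the last two axes of each trial.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("mixing weight must be in [0, 1]")
    s_norm = np.linalg.norm(signal, axis=(1, 2), keepdims=True)
    n_norm = np.linalg.norm(noise, axis=(1, 2), keepdims=True)
    s_norm = np.where(s_norm > 0, s_norm, 1.0)
    n_norm = np.where(n_norm > 0, n_norm, 1.0)
    return weight * signal / s_norm + (1.0 - weight) * noise / n_norm


def project_with_background(
    roi_epochs: EpochedSignals,
    gain: GainMatrix,
    alpha: float,
    beta: float | None = 0.9,
    seed=None,
) -> EpochedSignals:
    """Project region activity to sensors and blend background + sensor noise.

    ``alpha`` weighs the projected region signals against projected white
    Gaussian background activity (fresh per trial); ``beta`` then weighs that
    blend against iid per-sensor measurement noise. ``beta=None`` skips the
    measurement-noise step and returns the alpha-blend renormalized to unit
    Frobenius norm per trial (the quantity the measurement step consumes).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if beta is not None and not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    if roi_epochs.n_channels != gain.n_rois:
        raise ValueError(
            f"{roi_epochs.n_channels} region channels vs {gain.n_rois} gain columns"
        )
    rng = np.random.default_rng(seed)
    n_trials, _, n_samples = roi_epochs.data.shape
    n_bg = gain.background_gains.shape[1]

    y_rois = np.einsum("sr,nrt->nst", gain.roi_gains, roi_epochs.data)
    bg_src = rng.standard_normal((n_trials, n_bg, n_samples))
    y_bg = np.einsum("sb,nbt->nst", gain.background_gains, bg_src)
    y_b = snr_mix(y_rois, y_bg, alpha)

    if beta is None:
        norm = np.linalg.norm(y_b, axis=(1, 2), keepdims=True)
        out = y_b / np.where(norm > 0, norm, 1.0)
    else:
        meas = rng.standard_normal(y_b.shape)
        out = snr_mix(y_b, meas, beta)
    ids = tuple(f"s{i:03d}" for i in range(out.shape[1]))
    return EpochedSignals(data=out, fs=roi_epochs.fs, channel_ids=ids)


@dataclass(frozen=True)
class SensorROIs:
    """Per ground-truth region, the K nearest sensor indices."""

    sensors: tuple  # tuple of tuples of sensor indices
    k: int


def kns_rois(layout: SensorLayout, k: int) -> SensorROIs:
    """The K nearest sensors (Euclidean) to every region source.

    Ties are broken by sensor index (stable sort), making the sets
    deterministic. Overlapping sets are allowed but flagged with a warning,
    since they only arise when regions sit closer than the sensor spacing.
    """
    if not 1 <= k <= layout.n_sensors:
        raise ValueError(f"K must be in [1, {layout.n_sensors}]")
    sets = []
    for q in layout.roi_pos:
        d = np.linalg.norm(layout.sensor_pos - q, axis=1)
        order = np.argsort(d, kind="stable")
        sets.append(tuple(int(i) for i in order[:k]))
    flat = [s for roi in sets for s in roi]
    if len(set(flat)) != len(flat):
        warnings.warn(
            "nearest-sensor sets overlap between regions", UserWarning, stacklevel=2
        )
    return SensorROIs(sensors=tuple(sets), k=int(k))
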