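"""Sensor-space evaluation: FC maps, percentile graphs, ROC/AUC, comparisons.

The full FC map is the dense graph over sensors whose edge weights are the
magnitude of one connectivity measure, collapsed to one scalar per pair over
a frequency band (default aggregation: the maximum of the measure's
magnitude over the band around the simulated rhythm). Nested sparse graphs
are cut at the (100 m / M)-th weight percentile for m = 0..M; edges are
classified as true positives when their endpoints fall in the nearest-sensor
sets of two *different* ground-truth regions (any pair — transitivity of
functional coupling is accepted), otherwise false positives. TPR(m) =
TP(m)/TP(0), FPR(m) = FP(m)/FP(0), and the AUC is the trapezoidal area of
the (FPR, TPR) polyline with the (0,0) and (1,1) endpoints appended.

The Monte-Carlo harness repeats scenario realizations, averages AUC over a
range of neighborhood sizes, and compares measures/conditions with
Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired) tests under
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .core_spectra import EpochedSignals, SpectralEnsemble, center_epochs, epoch_fft
from .fc_measures import _measure_kernel, canonical_measure
from .mixing_forward import SensorROIs

__all__ = [
    "FCMap",
    "ROCResult",
    "MCComparison",
    "full_fc_map",
    "percentile_graphs",
    "classify_tp_fp",
    "roc_auc",
    "label_permuted_map",
    "mc_harness",
    "tally_scores",
]


@dataclass(frozen=True)
class FCMap:
    """Symmetric nonnegative sensors-by-sensors weight matrix."""

    weights: np.ndarray
    measure: str
    band: tuple
    aggregation: str = "max"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)

    @property
    def n_sensors(self) -> int:
        return self.weights.shape[0]

    def edge_list(self):
        """Upper-triangle edges as (i, j, weight) arrays."""
        iu, jv = np.triu_indices(self.n_sensors, k=1)
        return iu, jv, self.weights[iu, jv]


def _band_indices(freqs: np.ndarray, band) -> np.ndarray:
    lo, hi = band
    idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if idx.size == 0:
        raise ValueError(f"band {band} contains no frequency bin")
    return idx


def full_fc_map(
    sensors,
    measure: str,
    band,
    aggregation: str = "max",
    icoh2_norm: str = "per-trial",
    chunk: int = 256,
) -> FCMap:
    """One scalar edge weight per sensor pair.

    ``sensors`` is an :class:`EpochedSignals` (centered + FFT'd internally)
    or a ready :class:`SpectralEnsemble`. The measure's magnitude is
    aggregated over ``band = (lo_hz, hi_hz)`` with ``aggregation`` "max"
    (default), "mean", or "bin" (single bin nearest the band centre).
    Hilbert-based measures see the full frequency axis; only the aggregation
    is band-restricted.
    """
    m = canonical_measure(measure)
    if isinstance(sensors, EpochedSignals):
        spec = epoch_fft(center_epochs(sensors))
    elif isinstance(sensors, SpectralEnsemble):
        spec = sensors
    else:
        raise TypeError("sensors must be EpochedSignals or SpectralEnsemble")
    if spec.n_channels < 2:
        raise ValueError("need at least 2 sensors")
    idx = _band_indices(spec.freqs, band)
    if aggregation == "bin":
        centre = 0.5 * (band[0] + band[1])
        idx = idx[[int(np.argmin(np.abs(spec.freqs[idx] - centre)))]]
    elif aggregation not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    coeffs = spec.coeffs  # (N, C, F)
    mags = np.abs(coeffs)
    norm = np.where(mags > 0, coeffs / np.where(mags > 0, mags, 1.0), 0.0)
    auto = (mags**2).mean(axis=0)  # (C, F)

    c = spec.n_channels
    iu, jv = np.triu_indices(c, k=1)
    weights = np.zeros((c, c))
    for start in range(0, iu.size, chunk):
        pu = iu[start : start + chunk]
        pv = jv[start : start + chunk]
        cross = coeffs[:, pu, :] * coeffs[:, pv, :].conj()  # (N, P, F)
        ncross = norm[:, pu, :] * norm[:, pv, :].conj() if m == "plv" else None
        vals = _measure_kernel(
            m, cross, ncross, auto[pu], auto[pv], trial_axis=0,
            icoh2_norm=icoh2_norm, warn=False,
        )  # (P, F)
        mag = np.abs(vals[:, idx])
        agg = mag.max(axis=1) if aggregation == "max" else mag.mean(axis=1)
        weights[pu, pv] = agg
        weights[pv, pu] = agg
    return FCMap(weights=weights, measure=m, band=tuple(band), aggregation=aggregation)


def percentile_graphs(fc_map: FCMap, n_thresholds: int = 100) -> list:
    """Nested edge sets cut at the (100 m / M)-th weight percentile, m = 0..M.

    Edges with weight >= the percentile are kept (ties kept), so m = 0 is the
    complete graph; m = M is the empty graph by definition.
    """
    M = int(n_thresholds)
    if M < 1:
        raise ValueError("need at least 1 threshold step")
    iu, jv, w = fc_map.edge_list()
    edges = np.stack([iu, jv], axis=1)
    out = []
    for m in range(M + 1):
        if m == M:
            out.append(edges[:0])
            continue
        thr = np.percentile(w, 100.0 * m / M)
        out.append(edges[w >= thr])
    return out


def classify_tp_fp(edges: np.ndarray, rois: SensorROIs) -> tuple[int, int]:
    """Count true/false positive edges against nearest-sensor region sets.

    An edge is a true positive iff its endpoints lie in the sensor sets of
    two different regions (any region pair); edges within a single region's
    set, or touching a sensor in no set, are false positives.
    """
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    if edges.size == 0:
        return 0, 0
    max_sensor = int(edges.max()) + 1
    membership = np.full(max_sensor, -1, dtype=int)
    for r, sens in enumerate(rois.sensors):
        for s in sens:
            if s < max_sensor:
                membership[s] = r  # later regions win overlaps (rare, warned)
    a = membership[edges[:, 0]]
    b = membership[edges[:, 1]]
    tp = int(np.count_nonzero((a >= 0) & (b >= 0) & (a != b)))
    return tp, int(edges.shape[0] - tp)


@dataclass(frozen=True)
class ROCResult:
    """TP/FP counts over nested percentile thresholds plus the AUC."""

    tp: np.ndarray
    fp: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    kns: int


def roc_auc(fc_map: FCMap, rois: SensorROIs, n_thresholds: int = 100) -> ROCResult:
    """ROC over percentile-thresholded graphs and its trapezoidal AUC."""
    graphs = percentile_graphs(fc_map, n_thresholds)
    counts = np.array([classify_tp_fp(g, rois) for g in graphs], dtype=float)
    tp, fp = counts[:, 0], counts[:, 1]
    if tp[0] == 0 or fp[0] == 0:
        raise ValueError(
            "degenerate geometry: the complete graph has no TP or no FP edges"
        )
    tpr = tp / tp[0]
    fpr = fp / fp[0]
    # integrate over the polyline from (0,0) to (1,1)
    xs = np.concatenate([[0.0], fpr[::-1], [1.0]])
    ys = np.concatenate([[0.0], tpr[::-1], [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return ROCResult(
        tp=tp.astype(int), fp=fp.astype(int), tpr=tpr, fpr=fpr,
        auc=auc, kns=rois.k,
    )


def label_permuted_map(fc_map: FCMap, rng) -> FCMap:
    """Chance-level control: permute the sensor labels of the weight matrix."""
    perm = rng.permutation(fc_map.n_sensors)
    w = fc_map.weights[np.ix_(perm, perm)]
    return FCMap(
        weights=w, measure=fc_map.measure, band=fc_map.band,
        aggregation=fc_map.aggregation,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo comparison harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCComparison:
    """Per-configuration AUC samples and pairwise rank-test results.

    ``auc`` maps (scenario_name, measure) to an array of R realization AUCs
    (each already averaged over the KNS range); ``pairwise`` maps
    (scenario_name, measure_a, measure_b) to a dict with the signed-rank
    p-value (raw and Bonferroni-corrected) and the higher-median measure.
    """

    auc: dict
    pairwise: dict
    kns_range: tuple
    bonferroni_n: int


def mc_harness(
    scenarios,
    measures,
    n_realizations: int,
    kns_range=(6, 7, 8, 9, 10),
    seed=None,
    n_thresholds: int = 100,
    alpha_level: float = 0.05,
) -> MCComparison:
    """Repeat scenario realizations and rank-compare the measures.

    ``scenarios`` is a sequence of objects with a ``name`` attribute and a
    ``realize(measures, kns_range, n_thresholds, rng) -> dict[measure, auc]``
    method returning the KNS-averaged AUC of one fresh realization (see
    :class:`eicon.io.SensorScenario`). Paired measure comparisons use the
    two-sided Wilcoxon signed-rank test (same realizations under both
    measures); the Bonferroni factor is the number of tested pairs times the
    number of scenarios.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("empty scenario list")
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations for any test")
    measures = [canonical_measure(m) for m in measures]
    rng = np.random.default_rng(seed)

    auc = {}
    for scen in scenarios:
        samples = {m: np.empty(n_realizations) for m in measures}
        for r in range(n_realizations):
            vals = scen.realize(measures, kns_range, n_thresholds, rng)
            for m in measures:
                samples[m][r] = vals[m]
        for m in measures:
            auc[(scen.name, m)] = samples[m]

    pairs = list(combinations(measures, 2))
    n_tests = max(len(pairs) * len(scenarios), 1)
    pairwise = {}
    for scen in scenarios:
        for ma, mb in pairs:
            a = auc[(scen.name, ma)]
            b = auc[(scen.name, mb)]
            if np.allclose(a, b):
                p = 1.0
            else:
                p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
            p_corr = min(1.0, p * n_tests)
            winner = None
            if p_corr < alpha_level:
                winner = ma if np.median(a) > np.median(b) else mb
            pairwise[(scen.name, ma, mb)] = {
                "p": p, "p_bonferroni": p_corr, "winner": winner,
            }
    return MCComparison(
        auc=auc, pairwise=pairwise, kns_range=tuple(kns_range),
        bonferroni_n=n_tests,
    )


def tally_scores(outcomes) -> dict:
    """Win/loss/draw bookkeeping over pairwise games.

    ``outcomes`` is an iterable of (measure_a, measure_b, winner) with
    ``winner`` one of the two measures or None for a draw. Returns per
    measure the W-L-D record plus points under two systems: league (win 3,
    draw 1) and chess (win 1, draw 0.5).
    """
    records = {}

    def rec(m):
        return records.setdefault(m, {"W": 0, "L": 0, "D": 0})

    for a, b, winner in outcomes:
        if winner is None:
            rec(a)["D"] += 1
            rec(b)["D"] += 1
        elif winner == a:
            rec(a)["W"] += 1
            rec(b)["L"] += 1
        elif winner == b:
            rec(b)["W"] += 1
            rec(a)["L"] += 1
        else:
            raise ValueError(f"winner {winner!r} is neither {a!r} nor {b!r}")
    for r in records.values():
        r["league_points"] = 3 * r["W"] + r["D"]
        r["chess_points"] = r["W"] + 0.5 * r["D"]
    return records
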