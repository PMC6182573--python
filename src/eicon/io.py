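"""Serialization, scenario configuration and reproducible pipelines.

Formats: epoched arrays in HDF5 (dataset ``data`` [N x C x Nt], attributes
``fs`` and ``channel_ids``) or a directory of per-trial TSV files; curves,
thresholds and FC maps as TSV; scenario configuration as TOML; run logs and
summaries as JSON. All randomness flows from one root seed through named
substreams so every artifact of a run is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - python < 3.11
    import tomli as tomllib

from . import evaluation, mixing_forward, simulators, surrogates
from .core_spectra import EpochedSignals, center_epochs, epoch_fft

__all__ = [
    "seed_stream",
    "save_epochs_h5",
    "load_epochs_h5",
    "save_epochs_tsv_dir",
    "load_epochs_tsv_dir",
    "save_curve_tsv",
    "load_curve_tsv",
    "save_fcmap_tsv",
    "load_fcmap_tsv",
    "SensorScenario",
    "load_scenario_toml",
    "run_scenario",
    "make_fixtures",
]


def seed_stream(root_seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Array containers
# ---------------------------------------------------------------------------


def save_epochs_h5(path, epochs: EpochedSignals) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["fs"] = epochs.fs
        f.attrs["channel_ids"] = list(epochs.channel_ids)


def load_epochs_h5(path) -> EpochedSignals:
    with h5py.File(path, "r") as f:
        return EpochedSignals(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_ids=tuple(str(c) for c in f.attrs["channel_ids"]),
        )


def save_epochs_tsv_dir(path, epochs: EpochedSignals) -> None:
    """One TSV per trial (samples x channels, with a channel header row)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "meta.json").write_text(
        json.dumps({"fs": epochs.fs, "channel_ids": list(epochs.channel_ids)})
    )
    header = "\t".join(epochs.channel_ids)
    for n in range(epochs.n_trials):
        np.savetxt(
            path / f"trial{n:04d}.tsv",
            epochs.data[n].T,
            delimiter="\t",
            header=header,
            comments="",
        )


def load_epochs_tsv_dir(path) -> EpochedSignals:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    trials = sorted(path.glob("trial*.tsv"))
    data = np.stack(
        [np.loadtxt(t, delimiter="\t", skiprows=1).T for t in trials]
    )
    if data.ndim == 2:  # single channel: loadtxt squeezed
        data = data[:, None, :]
    return EpochedSignals(
        data=data, fs=float(meta["fs"]), channel_ids=tuple(meta["channel_ids"])
    )


# ---------------------------------------------------------------------------
# Curves, thresholds, maps
# ---------------------------------------------------------------------------


def save_curve_tsv(path, freqs: np.ndarray, columns: dict) -> None:
    """TSV with a freq_hz column plus named value columns."""
    names = ["freq_hz"] + list(columns)
    arr = np.column_stack([freqs] + [np.asarray(v, dtype=float) for v in columns.values()])
    np.savetxt(path, arr, delimiter="\t", header="\t".join(names), comments="")


def load_curve_tsv(path):
    with open(path) as f:
        names = f.readline().strip().split("\t")
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return arr[:, 0], {n: arr[:, i] for i, n in enumerate(names) if i > 0}


def save_fcmap_tsv(path, fc_map: evaluation.FCMap) -> None:
    iu, jv, w = fc_map.edge_list()
    arr = np.column_stack([iu, jv, w])
    np.savetxt(
        path, arr, delimiter="\t",
        header="sensor_a\tsensor_b\tweight", comments="",
        fmt=["%d", "%d", "%.17g"],
    )


def load_fcmap_tsv(path, measure: str = "coh", band=(0.0, 0.0)) -> evaluation.FCMap:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    n = int(arr[:, :2].max()) + 1
    w = np.zeros((n, n))
    ii = arr[:, 0].astype(int)
    jj = arr[:, 1].astype(int)
    w[ii, jj] = arr[:, 2]
    w[jj, ii] = arr[:, 2]
    return evaluation.FCMap(weights=w, measure=measure, band=tuple(band))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class SensorScenario:
    """A full source-to-sensors generative configuration.

    ``realize`` draws one fresh Monte-Carlo realization (new source noise —
    unless ``reuse_sources`` — new background and measurement noise),
    projects it to the synthetic sensor cap, builds the FC map per measure,
    and returns the AUC averaged over the requested neighborhood sizes.
    """

    name: str = "mvar3"
    model: str = "mvar"  # "mvar" | "nmm"
    n_rois: int = 3
    alpha: float = 0.5
    beta: float = 0.9
    n_trials: int = 100
    epoch_s: float = 1.0
    fs: float = 250.0
    n_sensors: int = 102
    n_background: int = 500
    band: tuple = None  # default: rhythm +/- 2 Hz per model
    aggregation: str = "max"
    layout_seed: int = 12345
    reuse_sources: bool = False
    nmm_coupling: float = 200.0
    _layout_cache: tuple = dataclasses.field(default=None, repr=False)
    _source_cache: object = dataclasses.field(default=None, repr=False)

    def __post_init__(self):
        if self.model not in ("mvar", "nmm"):
            raise ValueError("model must be 'mvar' or 'nmm'")
        if self.band is None:
            centre = 20.0 if self.model == "mvar" else 10.87
            self.band = (centre - 2.0, centre + 2.0)

    def layout(self):
        if self._layout_cache is None:
            self._layout_cache = mixing_forward.synth_layout(
                n_sensors=self.n_sensors,
                n_background=self.n_background,
                roi_positions=self.n_rois,
                seed=self.layout_seed,
            )
        return self._layout_cache

    def network(self) -> simulators.GroundTruthNetwork:
        if self.model == "mvar":
            return simulators.mvar_network(self.n_rois)
        return simulators.nmm_network(self.n_rois, coupling=self.nmm_coupling)

    def sources(self, rng) -> EpochedSignals:
        if self.reuse_sources and self._source_cache is not None:
            return self._source_cache
        if self.model == "mvar":
            spec = simulators.MVARSpec(network=self.network(), fs=self.fs)
            src = simulators.simulate_mvar(
                spec, self.n_trials, int(round(self.epoch_s * self.fs)),
                seed=rng.integers(2**31),
            )
        else:
            src = simulators.simulate_nmm_sdde(
                simulators.NMMParams(fs_out=self.fs),
                self.network(), self.n_trials, self.epoch_s,
                seed=rng.integers(2**31),
            )
        if self.reuse_sources:
            self._source_cache = src
        return src

    def realize_sensors(self, rng) -> EpochedSignals:
        _, gain = self.layout()
        src = center_epochs(self.sources(rng))
        return mixing_forward.project_with_background(
            src, gain, alpha=self.alpha, beta=self.beta,
            seed=rng.integers(2**31),
        )

    def realize(self, measures, kns_range, n_thresholds, rng) -> dict:
        layout, _ = self.layout()
        sensors = self.realize_sensors(rng)
        spec = epoch_fft(center_epochs(sensors))
        out = {}
        for m in measures:
            fc = evaluation.full_fc_map(
                spec, m, self.band, aggregation=self.aggregation
            )
            aucs = [
                evaluation.roc_auc(fc, mixing_forward.kns_rois(layout, k),
                                   n_thresholds).auc
                for k in kns_range
            ]
            out[m] = float(np.mean(aucs))
        return out


def roc_null_comparison(
    scenario: "SensorScenario",
    measures,
    n_realizations: int,
    kns: int = 6,
    seed: int = 0,
    n_thresholds: int = 100,
) -> dict:
    """Realization AUCs versus a sensor-label-permuted chance control.

    For each of ``n_realizations`` fresh realizations the FC map of every
    measure is scored against the nearest-sensor regions twice: as-is, and
    after permuting the map's sensor labels (which preserves the weight
    distribution but destroys the geometry). Returns per measure the arrays
    ``auc`` and ``null_auc`` plus the one-sided Mann-Whitney p-value of
    real > null.
    """
    from scipy import stats

    layout, _ = scenario.layout()
    rois = mixing_forward.kns_rois(layout, kns)
    rng = seed_stream(seed, "roc-null")
    real = {m: [] for m in measures}
    null = {m: [] for m in measures}
    for _ in range(n_realizations):
        sensors = scenario.realize_sensors(rng)
        spec = epoch_fft(center_epochs(sensors))
        for m in measures:
            fc = evaluation.full_fc_map(
                spec, m, scenario.band, aggregation=scenario.aggregation
            )
            real[m].append(evaluation.roc_auc(fc, rois, n_thresholds).auc)
            perm = evaluation.label_permuted_map(fc, rng)
            null[m].append(evaluation.roc_auc(perm, rois, n_thresholds).auc)
    out = {}
    for m in measures:
        a = np.asarray(real[m])
        b = np.asarray(null[m])
        p = float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
        out[m] = {"auc": a, "null_auc": b, "p_greater": p}
    return out


_SCENARIO_FIELDS = {
    f.name for f in dataclasses.fields(SensorScenario) if not f.name.startswith("_")
}


def load_scenario_toml(path) -> dict:
    """Parse a scenario TOML file into a validated config dict."""
    with open(path, "rb") as f:
        cfg = tomllib.load(f)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    allowed = _SCENARIO_FIELDS | {
        "seed", "measures", "kns_range", "n_thresholds", "surrogates",
        "n_realizations",
    }
    bad = sorted(set(cfg) - allowed)
    if bad:
        raise ValueError(f"unknown configuration keys: {', '.join(bad)}")
    return cfg


def run_scenario(config, out_dir) -> dict:
    """Execute one scenario end to end and write the artifact bundle.

    ``config`` is a dict (or path to a TOML file) with SensorScenario fields
    plus optional ``seed`` (default 0), ``measures`` (default ["icoh1",
    "eic2"]), ``kns_range``, ``n_thresholds`` and ``surrogates`` (count; 0
    skips thresholds). Writes sensor data (HDF5), per-measure FC maps and
    ROC tables (TSV), a JSON summary and the resolved config; returns the
    summary dict. Deterministic given (config, seed).
    """
    if not isinstance(config, dict):
        config = load_scenario_toml(config)
    config = validate_config(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    measures = [str(m) for m in config.get("measures", ["icoh1", "eic2"])]
    kns_range = tuple(config.get("kns_range", (6,)))
    n_thresholds = int(config.get("n_thresholds", 100))
    n_surr = int(config.get("surrogates", 0))
    scen = SensorScenario(
        **{k: v for k, v in config.items() if k in _SCENARIO_FIELDS}
    )

    layout, _ = scen.layout()
    sensors = scen.realize_sensors(seed_stream(seed, "realization"))
    save_epochs_h5(out / "sensors.h5", sensors)
    spec = epoch_fft(center_epochs(sensors))

    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.items()},
        "seed": seed,
        "auc": {},
    }
    for m in measures:
        fc = evaluation.full_fc_map(spec, m, scen.band, aggregation=scen.aggregation)
        save_fcmap_tsv(out / f"fcmap_{m}.tsv", fc)
        aucs = {}
        for k in kns_range:
            roc = evaluation.roc_auc(
                fc, mixing_forward.kns_rois(layout, k), n_thresholds
            )
            np.savetxt(
                out / f"roc_{m}_kns{k}.tsv",
                np.column_stack([np.arange(roc.tp.size), roc.tp, roc.fp,
                                 roc.tpr, roc.fpr]),
                delimiter="\t", header="m\tTP\tFP\tTPR\tFPR", comments="",
            )
            aucs[str(k)] = roc.auc
        summary["auc"][m] = aucs
        if n_surr > 0 and sensors.n_channels == 2:
            thr = surrogates.surrogate_threshold(
                spec, 0, 1, m, n_surrogates=n_surr,
                seed=seed_stream(seed, f"surrogates-{m}"),
            )
            save_curve_tsv(
                out / f"threshold_{m}.tsv", thr.freqs,
                {"upper": thr.upper, "lower": thr.lower},
            )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def make_fixtures(seed: int = 0) -> dict:
    """Small in-memory datasets with known structure, used by the test suite.

    Returns: ``ar_pair`` (2-channel, 8-trial coupled AR process),
    ``toy_layout``/``toy_gain`` (6-sensor cap with 2 regions), and
    ``tiny_ensemble`` (hand-written 3-trial, 8-bin spectral ensemble for
    brute-force measure oracles).
    """
    rng = seed_stream(seed, "fixtures")
    net = simulators.bivariate_mvar_network(coupling=0.5, delay=3)
    ar_pair = simulators.simulate_mvar(
        simulators.MVARSpec(network=net), n_trials=8, n_samples=250,
        seed=rng.integers(2**31),
    )
    layout, gain = mixing_forward.synth_layout(
        n_sensors=6, n_background=10, roi_positions=2,
        seed=rng.integers(2**31),
    )
    coeff_rng = seed_stream(seed, "tiny-ensemble")
    coeffs = (
        coeff_rng.standard_normal((3, 2, 8))
        + 1j * coeff_rng.standard_normal((3, 2, 8))
    )
    from .core_spectra import SpectralEnsemble

    tiny = SpectralEnsemble(
        coeffs=coeffs, freqs=np.arange(8.0), fs=16.0, channel_ids=("u", "v")
    )
    return {
        "ar_pair": ar_pair,
        "toy_layout": layout,
        "toy_gain": gain,
        "tiny_ensemble": tiny,
    }
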