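"""Preset demonstration analyses behind ``eicon reproduce``.

Each preset is a scaled, scriptable version of one of the package's core
demonstrations (the narrative versions live in ``examples/``): the envelope
recovery worked example, the delay sweep of the bivariate AR system, the
volume-conduction control, the phase/bandwidth grid of the band-limited
pair, and the scaled sensor-space ROC benchmark. All write TSV/JSON into an
output directory and are deterministic given the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io, mixing_forward, simulators
from .core_spectra import center_epochs, epoch_fft
from .fc_measures import hilbert_envelope, measure_curve
from .surrogates import surrogate_threshold


def run_preset(name: str, out: Path, seed: int = 0) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    {
        "envelope": _envelope,
        "delay-sweep": _delay_sweep,
        "volume-conduction": _volume_conduction,
        "phase-grid": _phase_grid,
        "roc-scaled": _roc_scaled,
    }[name](out, seed)


def _envelope(out: Path, seed: int) -> None:
    fs = 1000.0
    t = np.arange(1000) / fs
    belt = np.exp(-((t - 0.5) ** 2) / (2 * 0.02**2))
    x = np.sin(2 * np.pi * 40.0 * t) * belt
    env = hilbert_envelope(x)
    io.save_curve_tsv(out / "time_envelope.tsv", t,
                      {"signal": x, "belt": belt, "envelope": env.envelope})
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    ei = hilbert_envelope(spec.imag)
    io.save_curve_tsv(
        out / "imaginary_envelope.tsv", freqs,
        {"re": spec.real, "im": spec.imag, "ei": ei.envelope,
         "msd": np.abs(spec)},
    )


def _delay_sweep(out: Path, seed: int) -> None:
    for delay in range(1, 13):
        net = simulators.bivariate_mvar_network(coupling=0.5, delay=delay)
        src = simulators.simulate_mvar(
            simulators.MVARSpec(network=net), 100, 250, seed=seed + delay
        )
        mixed = mixing_forward.mix_two_sensors(
            center_epochs(src), seed=seed + 100 + delay
        )
        spec = epoch_fft(center_epochs(mixed))
        cols = {}
        for m in ("icoh1", "eic1", "icoh2", "eic2", "lcoh", "pli", "wpli"):
            cols[m] = measure_curve(spec, m, "u", "v").values
            thr = surrogate_threshold(
                spec, "u", "v", m, n_surrogates=200, seed=seed + 200 + delay
            )
            cols[f"{m}_upper"] = thr.upper
        io.save_curve_tsv(out / f"delay{delay:02d}.tsv", spec.freqs, cols)


def _volume_conduction(out: Path, seed: int) -> None:
    net = simulators.bivariate_nmm_network(coupling=0.0)
    src = simulators.simulate_nmm_sdde(simulators.NMMParams(), net, 100, 1.0,
                                       seed=seed)
    mixed = mixing_forward.mix_two_sensors(center_epochs(src), seed=seed + 1)
    spec = epoch_fft(center_epochs(mixed))
    cols = {}
    for m in ("coh", "plv", "icoh1", "pli", "wpli", "eic2"):
        cols[m] = measure_curve(spec, m, "u", "v").values
        thr = surrogate_threshold(spec, "u", "v", m, n_surrogates=1000,
                                  seed=seed + 2)
        cols[f"{m}_upper"] = thr.upper
    io.save_curve_tsv(out / "uncoupled_pair.tsv", spec.freqs, cols)


def _phase_grid(out: Path, seed: int) -> None:
    for lag in (0, 2, 4, 8, 16, 32):
        for bw in (0.5, 1.0, 2.0, 5.0):
            spec_cfg = simulators.BandlimitedSpec(
                bandwidth=bw, delay=lag, beta=0.5
            )
            s = simulators.simulate_bandlimited_pair(
                spec_cfg, 100, 250, seed=seed + lag * 10 + int(bw * 2)
            )
            spec = epoch_fft(center_epochs(s))
            io.save_curve_tsv(
                out / f"lag{lag:02d}_bw{bw}.tsv", spec.freqs,
                {
                    "icoh1": measure_curve(spec, "icoh1", "u", "v").values,
                    "eic2": measure_curve(spec, "eic2", "u", "v").values,
                },
            )


def _roc_scaled(out: Path, seed: int) -> None:
    scen = io.SensorScenario(name="mvar3", model="mvar", n_rois=3,
                             alpha=0.5, beta=0.9)
    res = io.roc_null_comparison(scen, ["icoh1", "eic2"], n_realizations=5,
                                 kns=6, seed=seed)
    summary = {
        m: {
            "median_auc": float(np.median(r["auc"])),
            "median_null_auc": float(np.median(r["null_auc"])),
            "p_greater_than_null": r["p_greater"],
        }
        for m, r in res.items()
    }
    (out / "roc_scaled.json").write_text(json.dumps(summary, indent=2))
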