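"""Delayed 20 Hz coupling seen by the different connectivity measures.

Two AR(2) sources oscillating near 20 Hz, with a directed coupling
y -> x at a 5-sample (20 ms) delay, are mixed into two sensors by the local
leadfield model. 20 ms is half the 20 Hz cycle, so the phase difference at
the interaction frequency sits near pi and the imaginary coherence crosses
zero exactly there — icoh1 reports nothing at 20 Hz even though the
coupling is real. The envelope measure eic2 keeps a strong value at the
rhythm (the sign-based pli/wpli still respond here because the AR
interaction is broadband, but they too collapse for narrow-band pi-phase
interactions; see example 04).
"""

import numpy as np

from eicon import (
    MixingCoeffs,
    MVARSpec,
    center_epochs,
    epoch_fft,
    measure_curve,
    mix_two_sensors,
    simulate_mvar,
    surrogate_threshold,
)
from eicon.simulators import bivariate_mvar_network
from eicon.surrogates import significant_at

net = bivariate_mvar_network(coupling=0.5, delay=5)
sources = simulate_mvar(MVARSpec(network=net), n_trials=100, n_samples=250, seed=0)
sensors = mix_two_sensors(center_epochs(sources), MixingCoeffs(), seed=1)
spec = epoch_fft(center_epochs(sensors))

print("measure   value@20Hz  threshold  significant")
for m in ("icoh1", "pli", "wpli", "lcoh", "eic2"):
    curve = measure_curve(spec, m, "u", "v")
    thr = surrogate_threshold(spec, "u", "v", m, n_surrogates=1000, seed=2)
    val = float(np.interp(20.0, curve.freqs, curve.values))
    up = float(np.interp(20.0, thr.freqs, thr.upper))
    sig = significant_at(curve, thr, 20.0)
    print(f"{m:8s}  {val:+.4f}     {up:.4f}     {sig}")
print("-> at a pi-phase delay icoh1 is blind at the interaction frequency;")
print("   the envelope measure eic2 still reports the 20 Hz coupling clearly")
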