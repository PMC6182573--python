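# Methods

## Estimation pipeline

All estimators operate on per-epoch one-sided Fourier coefficients. Epochs
are centred (mean removal per trial and channel — the only detrending),
transformed with a plain rectangular-window FFT (a Hann taper exists behind
`epoch_fft(..., taper="hann")` but defaults off), and never zero-padded, so
the frequency resolution is exactly fs/Nt (1 Hz for 1 s epochs at 250 Hz;
bins 0..125 Hz including DC and Nyquist). Ensemble averages over epochs play
the role of expectations. Degenerate bins follow fixed conventions, each
logged with a `DegenerateBinWarning`: coherence at a zero-power bin is 0;
wPLI 0/0 is 0; lagged coherence with denominator ≤ 1e-12 is 0; sgn(0) = 0;
an all-zero iCOH₂ normalization curve yields an all-zero measure. A guard
zeroes imaginary cross-spectrum entries below 1e-12 of the cross magnitude
so that sign-based statistics do not react to complex-multiply rounding
noise of exactly-real products.

## The envelope operator

The Hilbert envelope treats a real curve over the one-sided frequency grid
[0, fs/2] as an ordinary discrete sequence: analytic signal via the
standard FFT multiplier, envelope = magnitude. No padding is applied by
default; a reflective-padding flag exists for users who want damped edge
behavior. The envelope dominates the input pointwise (|h| ≥ |z| exactly),
which gives two structural guarantees: |iCOH₂| ≤ 1 pointwise (its per-epoch
envelope denominator dominates the numerator), and EIC_k ≥ |iCOH_k|. The
envelope of a curve bounded by 1 may itself exceed 1 near sharp ripples;
values are reported unclipped. On white-noise ensembles the overshoot stays
within ~5% (the bound asserted in the tests); on the broadband delayed AR
system we have observed EIC₂ maxima up to ≈ 1.16 at off-rhythm ripple —
users comparing EIC values across frequencies should treat it as a relative,
not absolute, scale.

In iCOH₂/EIC₂ the denominator applies the envelope per epoch to
Im{U_n V_n*}(f) and averages the magnitudes over epochs (`icoh2_norm=
"per-trial"`, the default); applying one envelope to the epoch-averaged
curve is available as `"post-average"` for sensitivity checks. The per-trial
placement follows the printed position of the expectation operator and is
the variant whose normalization tracks the per-epoch amplitude profile.

## Simulators

**Delayed MVAR.** Every region is x(t) = 1.5 x(t−1) − 0.75 x(t−2) + ε,
ε ~ N(0,1), at 250 Hz — complex poles at radius √0.75 ≈ 0.866 and ~20.8°,
spectral peak near 20 Hz. Directed edges add C·y(t−δ). Stationarity is
checked before simulation via the spectral radius of the companion matrix of
the full delayed system (simulation refuses radius ≥ 1, naming the radius).
History buffers start at zero and 2 s of burn-in per epoch is discarded.
Reference networks: 3 regions (C = ±0.1, δ = 2–3 samples) and 5 regions
(C = ±0.1, δ = 1–5), plus the bivariate motif (C = 0.5, δ configurable).

**Delayed stochastic Jansen–Rit.** Six first-order states per region: three
postsynaptic potentials x1..x3 and their derivatives x4..x6, with the
standard parameter set (A = 3.25 mV, a = 100 /s, B = 22 mV, b = 50 /s,
e0 = 2.5 /s, v0 = 6 mV, ρ = 0.56 /mV, C = 135 and the usual C1..C4 ratios),
mean input I = 220 /s, and a Wiener increment (scaled by A·a·σ_W·√dt)
entering the excitatory feedback state x5. Inter-regional coupling
C·x1_src(t−τ) also enters x5 after a pure transmission delay held in a ring
buffer initialized at the initial state. The damping of x6 uses the standard
−b²·x3; a `strict_printed_x6` flag switches to an −a²·x3 variant kept for
sensitivity checks. Integration is Euler–Maruyama at dt = 0.05 ms by default
(dt must divide the 4 ms output interval; smaller steps are configurable),
followed by an 8th-order Butterworth low-pass at 100 Hz (zero-phase) and
decimation to 250 Hz. The local potential x2 − x3 is returned. Halving dt
moves the trial-averaged spectral peak by < 0.5 Hz (tested), which is the
package's convergence criterion for the default step. Divergence (state
blow-up) raises an error advising a smaller dt.

σ_W is not a standard Jansen–Rit constant; it was fixed once by a shipped
calibration (`calibrate_wiener_scale`): over the grid {0.5, 1, 2, 5, 10,
20}, the largest value keeping the trial-averaged spectral peak of the
coupled two-region system (C = 200, τ = 20 ms) at 10.87 ± 0.5 Hz with
0.25 Hz resolution. That value is 2.0 (σ_W = 5 already drags the peak to
≈ 10.25 Hz) and is the `NMMParams` default.

**Band-limited pairs.** x is white Gaussian noise ideally band-passed in
the frequency domain (binary mask on ω ± ϖ/2; out-of-band power is zero to
rounding). The delayed copy y(t) = x(t−δ) is produced in the same pass by
rotating the in-band coefficients with exp(−j2πfδ/fs). Because the process
is constructed in the frequency domain, this delay is exact at every bin —
the cross-spectral phase at f is exactly 2πfδ/fs — and edge-artifact-free.
(A truncate-after-filtering implementation was tried and rejected: the
truncation re-spreads the spectrum and distorts per-bin phases enough to
destroy the exact π-phase zero crossing of the imaginary part that this
generator exists to probe.) The two sensors are u = a₁x + b₁y,
v = a₂x + b₂y (defaults 0.75/0.5/0.5/0.75, mixing determinant 0.3125),
then blended with fresh white noise: Y = β·Ys/‖Ys‖ + (1−β)·U/‖U‖ with
per-trial Frobenius norms; β ∈ {0.9, 0.5, 0.1} approximates +20/0/−20 dB.

## Sensor-space realization

The two-sensor local leadfield model adds Gaussian sensor noise whose sd
defaults to 10% of the noiseless mixed signal's sd (no published value
exists for these terms; the default is logged). Its key identity,
Im S_uv = (a₁b₂ − a₂b₁)·Im S_xy — exact per epoch for noise-free mixing —
is what makes the imaginary part mixing-proof, and is verified in the tests
both exactly (σ = 0) and statistically (N = 1000 epochs with noise).

The multi-sensor model is deliberately synthetic: sensors on a Fibonacci
lattice over a spherical cap, region sources on an interior ring (or user
positions strictly inside the shell), 500 background sources drawn in the
cap volume (the count is configurable; per-trial normalization makes the
α-blend insensitive to it), and gains g(s,q) = 1/(d(s,q)² + 0.02 r²) with
unit-norm columns. No anatomy, no dipole orientations, no boundary-element
modeling: the only property the nearest-sensor evaluation requires is that
gain ordering equals distance ordering, which holds by construction and is
tested exhaustively. Region activity is projected, blended with projected
background activity at weight α (0.1/0.5/0.9 ≈ −20/0/+20 dB), then with
per-sensor measurement noise at weight β (default 0.9), each blend between
per-trial Frobenius-normalized terms. Sensor regions are the K nearest
sensors to each source (K = 6 default, ties broken by sensor index).

## Surrogates

The no-consistent-phase null is simulated by re-pairing channel v's epochs
with a uniform random permutation per surrogate (within-epoch spectra
intact, cross-epoch correspondence destroyed; the identity permutation is
not excluded). Default 1000 surrogates; the threshold is the per-frequency-
bin extreme (percentile 1.0) with a lower branch for the signed measures,
and a percentile knob for users wanting e.g. 0.95. Epoch-mean auto-spectra
are permutation-invariant, so surrogate paths reuse them. With the max
statistic the per-bin false-positive probability is 1/(n_surrogates+1) by
exchangeability; the test suite verifies the pooled empirical rate.
`significant_at` evaluates curve and threshold at an arbitrary frequency by
linear interpolation between bins — necessary when the frequency of interest
(e.g. 15.625 Hz with a 1 Hz grid) falls between bins, where a measure whose
curve crosses zero exactly there would otherwise be misread from a flanking
bin.

## Evaluation

Full FC maps collapse each pair's curve to one scalar: by default the
maximum of the measure's magnitude over the rhythm band (simulated rhythm
± 2 Hz; mean-over-band and single-bin aggregations are available). The band
collapse is a package choice — no canonical rule exists — and is recorded in
the map's metadata. Sparse graphs keep edges with weight ≥ the (100m/M)th
percentile for m = 0..M−1 (ties kept, so m = 0 is the complete graph);
m = M is the empty graph by definition. An edge is a true positive iff its
endpoints lie in the nearest-sensor sets of two different regions (any
pair — transitivity of functional coupling accepted); everything else,
including within-region edges, is a false positive. TPR(m) = TP(m)/TP(0),
FPR(m) = FP(m)/FP(0); the AUC integrates the (FPR, TPR) polyline with
(0,0) and (1,1) appended, and is invariant under any strictly monotone
reweighting of the edges (tested). Degenerate region geometry (no possible
TP or FP at the complete graph) is an error.

The Monte-Carlo harness repeats scenario realizations (fresh source noise —
optionally reused for the expensive neural-mass signals — and always fresh
background and measurement noise), averages each realization's AUC over a
range of neighborhood sizes (default K = 6–10), and compares measures with
the two-sided Wilcoxon signed-rank test (paired: same realizations) under
Bonferroni correction, with Mann–Whitney used for unpaired condition
comparisons; `tally_scores` implements the win/draw bookkeeping (league:
win 3 / draw 1; chess: win 1 / draw 0.5). A sensor-label-permuted version
of each FC map provides an explicit chance-level control
(`label_permuted_map`, `roc_null_comparison`).

## Problem sizes and determinism

The shipped tests and the acceptance script run scaled configurations chosen
as the smallest that leave the qualitative outcomes stable: 100 epochs of
1 s for the AR and band-limited analyses (as in the reference conditions),
20 × 4 s epochs for neural-mass spectra (0.25 Hz resolution), 20 Monte-Carlo
realizations at 102 sensors for the ROC benchmark, and 10 seeded repetitions
for the significance-count properties. Every generator and the surrogate
permutation stream is driven by `numpy.random.default_rng` seeds; named
substreams (`eicon.io.seed_stream`) derive independent generators from one
root seed, so complete runs are bit-reproducible from (configuration, seed).

## What the synthetic data does not cover

The generators emulate rhythmic, stationary, epoch-wise-independent source
activity with linear instantaneous mixing and Gaussian noise. They do not
emulate anatomical leadfields or dipole orientation effects, 1/f background
spectra, non-stationary or burst-like dynamics, inter-epoch dependence, or
realistic sensor noise covariance. Passing tests therefore demonstrate the
estimators' mathematical behavior (volume-conduction robustness, 0/π-phase
sensitivity, calibrated surrogate thresholds, above-chance network recovery
under the stated forward model) — not performance on real recordings.

## Known limitations

* EIC is a relative scale: envelope overshoot beyond 1 occurs on ripply
  broadband curves (observed ≤ ~1.16) and edge bins carry analytic-signal
  border effects (heavier tails than the underlying magnitude spectrum).
* On broadband coupled sources the EIC₂ maximum sits on a flat top: the
  rhythm bin carries ≥ 85% of the global maximum for all tested delays, but
  the bin-level argmax can sit several Hz away; peak-location claims should
  use smoothed or relative criteria.
* Surrogate thresholds for highly phase-stable narrow-band interactions are
  conservative for EIC₂ (the envelope of the shuffled imaginary part remains
  large when amplitudes are stable), so EIC₂ significance near such rhythms
  is a strict test.
* The percentile-graph ROC treats edge weights as exchangeable across the
  map; measures with strongly frequency-dependent bias profiles should be
  compared within, not across, bands.
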