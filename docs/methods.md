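# Methods

## Gating model and simulator

Channel gating is modelled as a continuous-time Markov chain over a small
set of states, each carrying an integer conductance level (0 = closed,
1 = open; levels > 1 express simultaneous openings when the aggregate of
several channels is described). Transition rates are constants in s⁻¹,
optionally voltage-dependent through a per-edge exponential factor
rate(V) = rate₀·exp(V/V_slope) — the standard single-barrier form.
A patch holds N independent, identical channels; each channel's sample
path is drawn exactly by event-driven (Gillespie) simulation — waiting
times are exponential in the current state's exit rate, with no time
discretization — and the per-channel paths are merged into one aggregate
level sequence whose dwell durations sum to the requested duration
exactly. Channels start from the stationary distribution at the command
voltage, so simulated records are stationary from t = 0 and time-average
statistics are unbiased estimators of their ensemble values.

The default fixture is the two-state C⇄O scheme. No kinetic scheme is
claimed for any real channel: published single-channel work on the
polycystin complex reports conductances and open probabilities but no
rate constants, so the simulator's rates are fixtures chosen to make the
observables well sampled (50 s⁻¹ each way ⇒ Popen 0.5, mean dwell 20 ms,
~500 events per 10 s window), not biological estimates.

Currents are rendered ohmically: a level-L dwell at voltage V produces
L·G·(V − V_rev)·10⁻³ pA with G in pS and V in mV. Gaussian baseline noise
(default SD 0.25 pA, a realistic RMS for an excised-patch recording at
5 kHz bandwidth and enough to keep the closed/open peaks ≥ 6 SD apart at
±20 mV for a ~96 pS channel) is added per sample, then a 4-pole Bessel
low-pass at the acquisition cutoff is applied, mimicking an amplifier
filter chain. With the conventional settings — 5 kHz cutoff, 10 kHz
digitization — the cutoff sits exactly at Nyquist, so the digital filter
is an identity and the noise SD parameter is the observed per-sample SD;
oversampled acquisitions are genuinely filtered. Level sampling reads the
dwell sequence at sample-interval midpoints, which makes round trips of
sample-aligned dwells exact.

The macroscopic (whole-cell) generator produces one sweep per step
voltage: holding segment, a 150 ms step during which
I(V,t) = I_ss(V)·(1 − e^(−t/τ)) rises monoexponentially, and a tail
segment relaxing toward the tail potential's steady state with the same
τ. I_ss(V) = g(V)·(V − V_rev) with a Boltzmann conductance
g(V) ∝ 1/(1 + e^(−(V − V_half)/k)) (defaults V_half = +60 mV, k = 40 mV)
gives the outward rectification typical of the polycystin complex; the
curve is normalized so the steady-state current at the reference voltage
(+180 mV) equals density × capacitance exactly, making noiseless
round-trip checks exact. Noiseless sweeps are returned unfiltered so the
ground truth is bit-exact. Capacitive transients and series-resistance
artifacts are not modelled.

## Amplitude analysis and idealization

All-points histograms use a Freedman–Diaconis default bin width, capped
at range/60: FD assumes a unimodal spread and over-widens bins badly on
well-separated open/closed peaks. Counts always sum to the sample count.

The Gaussian mixture is fitted by nonlinear least squares (trust-region
reflective) to the density-normalized histogram, offset C bounded at ≥ 0,
areas ≥ 0, and each σ bounded below by half the bin width so no component
can collapse onto a single bin. Starting means are picked greedily at the
highest-density points subject to a minimum separation; starting σ is
deliberately narrow (the optimiser widens a component far more reliably
than it splits an overly wide one). Non-convergence is flagged on the
returned object and warned about, never silent. The unitary current is
the difference of the two component means nearest baseline (the
component closest to 0 pA), so its sign follows the current's sign at
that voltage; a single-component fit raises an explicit
"no opening detected" error rather than returning 0.

Idealization is half-amplitude threshold crossing: thresholds midway
between adjacent fitted level means, each sample assigned a level, runs
compressed to dwells. Events shorter than the dead time are merged into
the longer neighbour, shortest first, until all interior dwells resolve.
The default dead time is the Gaussian-filter rule T_d = 0.179/f_c
(35.8 µs at 5 kHz) — below one sample interval at 10 kHz, so it only
bites on oversampled data. Level means closer than 3× the widest σ set
an overlap warning. No hidden-Markov idealization or dwell-time
likelihood fitting is attempted.

## Open-probability statistics

For a window of length T (default: 10 s of the record, starting point
user-selectable): the level-weighted open time is To = Σ_L L·T_L, the
fully-closed time Tc = T₀, and

- Popen = To/(N·T), with N = 1 reducing bit-exactly to the
  single-channel To/T;
- NPo = To/(To + Tc), implemented literally with the level-weighted To.
  When multi-level openings occur To + Tc exceeds T, so NPo is not a time
  fraction; a strict per-sample alternative (fraction of time any channel
  is open) is available behind a flag. Both statistics are computed and
  labelled distinctly because conventions differ between labs.

N defaults to the maximum observed idealized level (how channel counts
are usually assigned in practice), overridable; supplying an N smaller
than an observed level is an error naming both values.

Slope conductance is the unweighted OLS slope of unitary current (pA)
against voltage (mV), × 10³ = pS, fitted over −100..+100 mV by default
with optional limb-restricted ranges for rectifying channels. Voltages
where the expected unitary current is within 4 noise SD of baseline
(including V = V_rev) are skipped in the pipeline's i–V assembly — the
two peaks are not separable there and a forced two-component fit would
only inject noise into the line fit.

## Whole-cell analysis

Peak current per step is the largest-|I| sample inside the step window
(sign preserved) after blanking 2 ms at each step edge, the conventional
guard against capacitive transients in recorded data. Current density is
I/Cm. The activation fit minimizes Y(t) = Y₀ + A·e^(−t/τ) over a
user-given window with τ > 0 enforced; τ is initialized from a log-linear
regression of the de-trended segment. The widely printed form of this
equation swaps the names of the exponent's numerator and denominator; it
is implemented as the standard monoexponential with τ the time constant
in ms, which is what reported values mean. Flat segments are returned
flagged as unidentifiable (A ≈ 0) rather than raising, and a τ pinned at
its bounds clears the converged flag. In the simulation pipeline the fit
window starts at the step onset with no blanking, because simulated
sweeps carry no capacitive transient. Reversal potentials come from the
ramp I–V, boxcar-smoothed over 1 mV, by linear interpolation of the
sign change; with several crossings the one nearest 0 mV is returned
with a multiplicity flag, and no crossing is an explicit out-of-range
error. No leak subtraction or permeability-ratio modelling is included.

## Numerical and design choices

- All randomness flows from one root seed through `numpy` SeedSequence
  spawning (independent per-channel and per-sweep streams); identical
  seeds give byte-identical outputs, recorded with a config hash in every
  table and in the run manifest.
- Units: pA, mV, pS, ms (fits) / s (dwells), pF; outward current
  positive.
- Text ATF-style trace files (declared sampling rate cross-checked
  against the time column to 1 ppm; units validated per column) keep
  runs diff-able; no binary reader is bundled.
- Problem sizes in the test and acceptance runs: 10 s per voltage at
  10 kHz for conductance recovery; 10⁴ replicate paths for the
  matrix-exponential check; 100 replicates for noisy-τ recovery. The
  τ-recovery study samples at dt = τ/5 so the rising phase is resolved —
  at 10 kHz a 0.06 ms time constant leaves ≈ 1 sample on the rise, which
  is fine for a noiseless fit but hopeless at finite noise.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the estimators assume:
discrete conductance levels, exponential dwell times, stationary gating,
white Gaussian baseline noise, ohmic unitary currents, monoexponential
macroscopic activation. Passing recovery tests therefore demonstrates
the estimators are correct under those assumptions. Real recordings
violate them in ways the simulator deliberately omits: baseline drift
and seal instability, capacitive transients, flicker/1-f noise, subconductance
states, modal gating, and filter-shaped (non-white) noise. Results on
real data depend on those effects; the optional baseline handling and
dead-time controls mitigate but do not remove them.
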