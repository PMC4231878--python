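# Methods

## Model structure and assumptions

`lifesim` is a *functional* simulator: it reproduces the statistical
structure of multi-unit intrafascicular recordings without biophysics.
Three deliberate simplifications define its scope:

* Motor intent is a graded, normalized command vector, not a spike train;
  indirect motor pathways are not modeled.  The map to motoneuron
  activation is linear (`x = G u`), with activation clipped to 1 (and a
  logged warning) if gain rows sum above unity, since the rate curves are
  defined on [0, 1].
* All temporal shape of an extracellular spike lives in its template;
  electrode geometry, tissue filtering and fiber caliber are folded into
  that waveform.  One axon has one morphology on all electrodes (scaled
  copies only) — per-electrode morphology differences are out of scope.
* Electrode physics reduces to static gains: distance, drift and
  encapsulation are attenuation factors inside `B`/`H`.  There is no
  time-varying drift, impedance model, or thermal-noise physics.

## Rate curves and recruitment

The piecewise-linear curve passes through `(x_thr, f_thr)` and
`(x_sat, f_sat)`: `f(x) = f_thr + κ_f (x − x_thr)` on the rising branch
with `κ_f = (f_sat − f_thr)/(x_sat − x_thr)`.  A unit is recruited
*strictly above* its threshold (`f(x_thr) = 0`): the threshold is the
activation above which firing begins, which also makes threshold-level
steady states (e.g. an FF pool held exactly at its recruitment point)
unambiguously silent.

## Point-process timing

Spike trains are realized sequentially: at the current time the rate is
evaluated, an ISI with mean `1/f` is drawn, and the next event is placed
one interval later; silent stretches are skipped to the next recruited
sample, and the first event falls one drawn interval after recruitment
onset (the timing of the first spike is otherwise unconstrained by the
model).  Freezing the rate at the previous event is the standard
approximation for slowly varying drive; it is exact for the steady-level
benchmarks.

ISI distributions: identity (regular train, for testing), exponential
(Poisson), Gaussian, Gamma (mean ξ, sd σ → shape `(ξ/σ)²`, scale `σ²/ξ`),
and uniform on `[ξ − w/2, ξ + w/2]`.  The last three decouple ISI
variability from the mean.  Every stochastic draw is clipped to a 1 ms
floor — a minimal refractory stand-in that prevents an axon from
overlapping itself.  Clipping (rather than conditional truncation or
resampling) biases the mean ISI by only ~`c²/2ξ` (≈ 0.02 ms at 35 Hz for
the exponential), so empirical mean rates track `1/f` to within Monte
Carlo error; conditional truncation of an exponential would shift the
mean by the full floor.

Pool sampling draws each parameter independently and uniformly within its
range; draws violating `x_thr < x_sat` or `f_thr ≤ f_sat` are redrawn
pairwise (up to 100 times, then a configuration error), preserving
marginal uniformity over valid configurations.

## Templates

Morphologies are derivatives of Gaussian (default center 0.5, width 0.1
on the normalized support) or Gamma (shape 3, scale 0.08) kernels,
differentiated numerically, zero-meaned, then peak-normalized — in that
order, once per resampling, which guarantees zero discrete integral and
unit peak on any grid.  The shipped defaults reproduce three classes:
symmetric one peak/one trough (Gaussian, 1st derivative), symmetric two
peaks/two troughs (Gaussian, 3rd), asymmetric one peak/one trough (Gamma,
1st); the kernel shape parameters behind these classes are a free choice
and are configurable.  Scaling resamples by linear interpolation to
`round(duration × rate)` samples and rescales the peak to the amplitude
(arbitrary recording units — all downstream SNR arithmetic is unit-free).
Events are aligned to the nearest grid sample; at the default 20 kHz the
≤ 25 µs jitter is negligible against 2–6 ms templates.

## Electrode unit and noise

`H = C B` exactly; with `C = I` (the usual intrafascicular case, one pool
per electrode) `H = B`.  Power-law noise is synthesized spectrally (white
Gaussian shaped by `|f|^(−β/2)`, DC bin zeroed, Hermitian by construction)
and scaled to the requested standard deviation.  SNR-calibrated noise is
white Gaussian, band-limited by a zero-phase 4-pole Butterworth, then
rescaled so its SD equals `(Q_99.9 − Q_0.1)/(3·SNR)` of that electrode's
noise-free trace — per electrode, which makes the "average over
electrodes" reading hold automatically and is the only reading that is
well-defined per channel.  The 3 in the denominator is taken as given by
the convention.  Noise is independent across electrodes by default (the
shared mode reuses one realization); a silent electrode has no defined
SNR, so SNR-relative noise on a null-intent run is an error by design —
use an absolute-amplitude model there.

## Metrics

"Spike present" means the sample lies in the half-open window
`[event, event + duration)`, which avoids double counting at window
boundaries; percent overlap is the fraction of samples where ≥ 2 axons
are present.  The band-pass is a 4-pole Butterworth applied
forward-backward (zero phase, so overlap/timing statistics are unaffected;
the effective magnitude roll-off is doubled).  Welch spectra use 0.5 s
windows with 50% overlap; band power integrates the one-sided PSD over
80 Hz–4 kHz after filtering, matching the pipeline order (filter, then
Welch).  The decoder squares the trace (absolute value available),
averages over a 200 ms boxcar with nearest-value edge padding, and
min-max normalizes per trial; squaring is used because signal energy, not
amplitude, tracks composite firing rate.

## Scenario design choices

* **Ramp scenario (5 electrodes).** Contribution weights are equally
  spaced on [0.5, 1] per electrode; a single-axon electrode gets 1.0 (the
  equal-spacing rule is ill-defined for one value, and a lone resolved
  fiber is best modeled as close and unencapsulated).  S units use the
  symmetric one-peak morphology and FF units the asymmetric one, so fiber
  types are visually distinct in composite traces.
* **Overlap sweep (15 electrodes × 10 levels).** Each fiber group is one
  pool of 10 axons and the 2/4/6/8/10-axon electrodes record nested
  subsets; per-axon random streams are keyed by (seed, axon) and restarted
  at each level.  Consequently overlap is *exactly* monotone in axon count
  within a group, and *exactly* flat across levels at which every unit of
  a pool is saturated — the structural claims of the sweep hold by
  construction rather than within sampling error.  Mixed pools interleave
  S and FF so a k-axon prefix splits evenly, remainder to S.  Each level
  runs 10 s by default, long enough for overlap standard errors below one
  percentage point at the rates involved.  Levels are constant-intent
  segments, not a ramp, since the statistic is defined per level.
* **Steady-state spectral benchmark (30 electrodes × 3 levels).** Pool
  parameters approximate chronic recordings in which every electrode shows
  graded activity across effort levels: fiber-type-specific durations,
  amplitudes and rate ranges as in the ramp scenario, but recruitment
  thresholds of 0–10% and saturations of 80–100% for both types, with
  steady levels at 0.25/0.5/0.75 — every unit is active and unsaturated at
  all three levels, so composite rate rises strictly with intent.  Each
  trial is 1 s quiescent + 3 s steady; the noise SD is calibrated once per
  electrode (SNR 3 against its highest-level pure trace) and held fixed
  across levels, because a physical electrode's noise floor does not track
  effort.  This fixed floor is what produces the characteristic spectral
  trend: spike energy sits low in the 80 Hz–4 kHz band while the noise is
  broadband, so as intent grows, total power rises and the power-weighted
  mean frequency falls.

## What the synthetic benchmarks do and do not show

The generators emulate the *collision statistics*, *mixing structure* and
*spectral balance* of multi-unit recordings.  They do not emulate real
electromyographic interference, electrode drift dynamics, firing-rate
adaptation, conduction delays, or common synaptic drive (units are
conditionally independent given the intent).  Passing tests therefore
certify the simulator's internal laws (superposition, calibration,
determinism) and the qualitative phenomena that follow from rate/duration
arithmetic — not fidelity to any particular subject's recordings.

## Numerical notes

* Default grid: 20 kHz (Nyquist-safe for 100 Hz–10 kHz spike bandwidth),
  uniform, shared by all components of a run.
* Determinism: one master seed; spike trains use substreams keyed
  (seed, 0, unit index), noise (seed, 1, electrode), pool sampling
  (seed, 2, …) — adding electrodes or noise never perturbs spike trains.
* Zero-integral tolerance: `|Σ samples| < 1e-9 × peak × n` (float
  accumulation only; the mean is subtracted explicitly).
* Degenerate inputs raise typed errors rather than propagating NaNs:
  constant traces in SNR calibration, zero-variance quiescent segments,
  sub-sample durations/windows, unsatisfiable sampling ranges.

## Known limitations

Sequential-ISI generation slightly misplaces events under drive that
changes rapidly within one ISI (thinning would be exact but is
unnecessary at the intent bandwidths simulated here).  Overlap is a
binary per-sample statistic and does not grade constructive versus
destructive collisions.  The moving-average decoder is intentionally
minimal — the package exists to test external decoders, not to ship one.
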