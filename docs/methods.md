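# Methods

This note documents the models, processing choices and limitations of
`mwlkit`: what each workload measure assumes, what the synthetic
session generator does and does not emulate, and the numerical
conventions that make the pipeline deterministic.

## Session model

A session is five contiguous phases — PreRest (5 min), three mission
phases (10 min each) of increasing difficulty, PostRest (5 min) — on a
common clock starting at 0 s.  All intervals are half-open
[t, t + Δ); a stamp on a phase boundary belongs to the later phase.
The latent workload is a piecewise-constant level in [0, 1] per phase.
Constant-per-phase is the simplest driver consistent with a phase-level
analysis; the default levels are (0.05, 0.2, 0.55, 0.9, 0.15).  The
post-rest default (0.15) is deliberately above the pre-rest level:
operators do not return to baseline immediately after a demanding
mission, and the analysis should not assume they do.

## EEG index

**Model.** Mental workload raises frontal/central theta-band power
(4–7 Hz at F4, C4) and suppresses occipital alpha-band power (8–12 Hz
at O1, O2).  The index is the ratio of the two average band powers per
5-s window, so it rises with workload through both numerator and
denominator.  Being a ratio of powers from the same amplifier, it is
invariant to any global gain (verified to 1e-6 relative tolerance).

**Processing chain and choices.**

* Bandpass 0.5–30 Hz: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), zero phase, length preserving.  Order and family are
  implementation choices; the passband is the protocol value.
* Windows: non-overlapping contiguous 5-s windows; a trailing
  remainder shorter than one window is discarded, not zero-padded.
* Band power: linear detrend of the 5-s window, then Welch PSD with
  1-s Hann sub-windows at 50% overlap, integrated over the band by the
  trapezoidal rule.  Welch (rather than a single periodogram) keeps
  the per-window variance manageable at the 5-s scale.  Spectral
  leakage under the Hann taper costs ~8% of a pure tone's power at the
  band edges; the effect cancels in the ratio.
* Outlier replacement: one pass; mean and sample SD over the full
  series; values strictly beyond mean ± 3 SD — and windows flagged
  invalid (e.g. a non-positive alpha denominator) — are replaced by
  the mean of the retained values.  The global (not local) mean is
  used.  A constant series (SD = 0) has no outliers by convention.
* Smoothing: zero-phase moving average, default 60 s, edges use
  shrinking windows so the length is preserved and a constant series
  is a fixed point.  A moving average is parameter-light and
  sufficient to expose the phase-scale trends; the width is a config
  knob.

## Visual entropy

**Model.** Gaze transitions between regions of interest (ROIs) form a
first-order Markov chain; its conditional entropy, weighted by the
empirical prior over source ROIs, measures scanpath randomness in
bits.  A strictly cyclic scan has H = 0; a uniform row over n − 1
targets has H = log₂(n − 1).  H grows with workload as the operator
abandons a systematic scan.

**Choices.**

* Eye combination: midpoint of both valid eyes; a single valid eye is
  used as-is; samples with neither eye valid are excluded.
* ROI membership: half-open rectangles, listed priority order resolves
  overlap; coordinates are normalized to the unit square.
* Transitions are computed on *dwells*, not raw samples: consecutive
  same-ROI samples merge, making self-transitions structurally zero
  and the measure independent of the tracker's sampling rate.
* Gap rule: invalid/off-ROI samples form gaps.  A dwell continues
  across a gap of at most 1 s (blinks, brief dropouts); a longer gap
  restarts the sequence without emitting a transition across it, so
  data loss cannot fabricate transitions.
* Windowing: sliding 60-s windows every 5 s over the transition
  events, each summarized by the plug-in entropy of its count matrix
  (no smoothing of the matrix).  Windows with fewer than 5 transitions
  are flagged invalid.  Window length and the minimum count are config
  knobs; the defaults let phase-scale trends survive while keeping the
  per-window estimate usable.  The plug-in estimator is biased low for
  sparse windows; with the default scanpath statistics (~100
  transitions per window) the bias is a few hundredths of a bit.

## Secondary-task index

Each UAV's flight-log record is scored on six categories: navigation
accuracy (>25 m → 1; 10–25 m → 0.5; <10 m → 0), comm strength
(<50% → 1; 50–70% → 0.5; >70% → 0), fuel margin
r = fuel_onboard / fuel_needed (r < 1.5 → 1; 1.5 ≤ r < 2 → 0.5;
r ≥ 2 → 0), autopilot in hold (1), not assigned to a team (1), no
active sensors (1).  Band edges are resolved lower-inclusive (exactly
10 m or 25 m is "adequate"; exactly 50% or 70% is "adequate");
fuel_needed = 0 counts as an infinite, adequate margin.  The fuel rule
is expressed as a safety-margin ratio — the only reading under which
"adequate fuel" is the safe state.  The session-level index is the sum
over all UAVs released so far (the per-UAV cap of 6 is not a fleet
cap), sampled on a 5-s grid by carrying each UAV's latest record
forward.

## Controller inputs

Left and right clicks are counted together in half-open 2-min bins.
No command-vs-panning discrimination is attempted.

## Normalization, fusion, statistics

* Time series entering fusion and correlation are min-max normalized
  to [0, 1] over their valid points; a constant series is an error.
  z-normalization (mean 0, SD 1, sample SD) is reserved for per-phase
  means entering the ANOVA.
* All series are aligned on a common 5-s grid over the session span:
  series natively on the grid are taken as-is; coarser step-valued
  series (task index before resampling, click bins) are expanded by
  last-observation-carried-forward.  Grid points where either member
  of a pair is invalid are dropped pairwise.
* Fusion is the convex weighted sum of two aligned normalized series;
  the offered weight sets are 50/50, 70/30 and 30/70 for both the
  physiological pair (EEG index + entropy) and the objective pair
  (task index + clicks).
* Pearson correlation uses the standard product-moment formula and
  requires ≥ 3 paired points and non-constant inputs.  Per-pair values
  are aggregated across participants as mean ± sample SD (n − 1); the
  SD is undefined (NaN) for a single participant.
* The one-way ANOVA is a plain fixed-effects sum-of-squares
  decomposition treating participant-phase means as independent
  observations (groups = phases, replicates = participants), matching
  a reported df structure of (2, 12) for 5 participants × 3 phases.
  This ignores the repeated-measures structure of the design; a mixed
  model would be more efficient but is out of scope.  Tukey HSD uses
  the pooled within-group mean square and the studentized-range
  distribution (Tukey–Kramer form for unequal group sizes).
* Within a *single* synthetic session, the recovery tests run the
  phase ANOVA on the 5-s window values of each measure grouped by
  phase.  These values are autocorrelated (smoothing, LOCF), so the
  nominal p-values overstate significance; the test is a design
  property check on synthetic data, not an inferential claim.

## Synthetic session generator

The generator encodes one latent workload profile in four independent
streams.  Every generator is a pure function of (config, seed); the
master seed is split into fixed-order per-stream children so adding a
stream never perturbs the others.

* **EEG** (128 Hz, 16 channels of the 10–20 montage): 1/f pink noise
  (unit RMS, exponent 1) plus white noise (0.3 µV) on every channel; a
  6-Hz theta tone on F4/C4 with amplitude 1 + 1.0·w µV and a 10-Hz
  alpha tone on O1/O2 with amplitude 4 − 1.5·w µV (w = workload).
  Each rhythm's amplitude is additionally multiplied by a slow mean-1
  Ornstein–Uhlenbeck modulation (fractional SD 0.12, correlation time
  45 s, shared across the rhythm's channels): real band power waxes
  and wanes spontaneously, and this drift — not broadband noise — is
  what limits how faithfully a smoothed band-power index can track
  workload.  The modulation depth was set so the two physiological
  measures have comparable fidelity — the regime in which multi-sensor
  fusion is informative and which field studies of these two measures
  typically find — while the index under constant workload keeps a
  coefficient of variation below 0.3.  Sparse Gaussian artifact pulses (0.1/min, 150 µV,
  0.1 s) exercise the outlier replacement.
* **Gaze** (60 Hz, six ROIs in a 2×3 grid): a Markov scanpath with
  exponential dwells (mean 0.5 s).  Each transition row puts
  1 − ε on the next ROI of a fixed cycle and spreads ε uniformly over
  the others, with ε = 0.05 + 0.6·w clipped to [0, (n−2)/(n−1)]; the
  chain's conditional entropy is then strictly increasing in w, from a
  near-cyclic scan to near-uniform scanning.  Tracker dropout is
  generated in contiguous bursts (two-state Markov mask, mean burst
  0.2 s, stationary fraction 2%) with both eyes invalid — emulating an
  operator drifting out of camera range — plus 1% independent
  single-eye dropout.
* **UAV logs** (one record per UAV per 5 s): fleets of 3/6/9 UAVs
  released at the mission phase starts.  Each penalty category
  degrades with hazard 0.3 + 0.3·w events per UAV-minute and
  self-repairs after an exponential time (mean 45 s, the operator
  clearing the task).  Graded categories draw a half- or full-penalty
  severity with equal probability.  With these defaults the fleet
  index grows roughly linearly across mission phases, dominated by
  fleet size: the number of routine maintenance tasks scales with the
  number of platforms under supervision.
* **Clicks**: an inhomogeneous Poisson process with rate
  0.1 + 0.7·w Hz, simulated by thinning; 70% left button.
* **Ratings**: per-mission-phase subjective workload and situational-
  awareness means (2.9/5.9/7.8 and 9.6/6.2/4.0 on 0–10 scales) with
  0.5 SD noise, clipped to the scale.

**What the generator does not emulate.** EEG topography beyond the
four index channels, realistic blink/EMG artifact morphology,
volume-conduction correlations between channels; saccade kinematics,
fixation microstructure, pupil measures; UAV kinematics, path
planning, or any mission dynamics beyond category state flips;
inter-participant trait differences (participants differ only by
seed).  Consequently, passing recovery tests shows the *pipeline*
recovers a latent workload signal under realistic noise structure —
not that these measures work on any particular real recording.

## Problem sizes

The recovery study runs 20 independent synthetic participants at full
session length (30 min streams: ~4.9 M EEG samples, ~144 k gaze
samples, ~4 300 flight-log records per session).  End-to-end
determinism is exercised on a shortened session (8 min) since
byte-reproducibility is scale-independent.  Statistical oracles run on
100 random small datasets each.

## Known limitations

* The outlier pass is a single global pass; a drifting index could
  mask genuine outliers (the smoothed trend is not removed first).
* Entropy windows are stamped at their start; measures are therefore
  aligned to within half an entropy window at phase boundaries.
* The fixed-effects ANOVA treats repeated measures as independent
  (documented above).
* Min-max normalization is sensitive to single extreme values; it is
  applied after outlier replacement for the EEG index but the task
  index and click counts are normalized raw.
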