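# Methods

This note documents the models, conventions and numerical choices behind
`kinencode`, including the choices that were genuinely open and the reasons
for settling them the way we did.

## Time base and grids

All times are seconds (floats); a session nominally starts at t = 0. The
analysis grid has bin width Δ = 30 ms (`bin_width_s`). The grid times
`grid_t` are simultaneously the instants at which kinematic series are
sampled and the centres of the half-open spike-count bins
[t_i − Δ/2, t_i + Δ/2). Centring the count bin on the kinematic sample
keeps the two signals phase-aligned: with any half-bin offset between the
conventions, every recovered lag acquires a systematic +0.5–1 bin bias
(we measured exactly that before adopting this convention). A spike landing
exactly on a bin edge is counted in the bin that edge opens.

## Kinematics

* **Resampling.** Tracking (nominally 30 frames/s) is linearly interpolated
  onto the grid. Gaps longer than three nominal frame intervals are treated
  as dropouts: bins inside them are masked and excluded pairwise from every
  correlation, never interpolated across. How real acquisition systems
  handle dropouts varies; masking is the conservative choice.
* **Smoothing.** x and y are smoothed with a centred 3-bin moving average
  (`smoothing_window_bins`, set 1 to disable) before differentiation.
  Second derivatives of raw 30 frames/s tracking are noise-dominated; a
  short symmetric window suppresses that without introducing any phase
  shift.
* **Differentiation.** Central differences, (s[i+1] − s[i−1])/2Δ, one-sided
  at the two edges. Central differences are phase-neutral, so lag estimates
  downstream are unbiased; a forward difference would shift every lag by
  half a bin. Acceleration is the central difference of the velocity
  series (not an independent second difference of position); the two differ
  only at mask edges, and differencing the velocity keeps mask propagation
  simple (each differentiation invalidates the neighbours of masked bins).
* **Rectified components.** vel_right = max(vx, 0), vel_left = max(−vx, 0),
  vel_up = max(vy, 0), vel_down = max(−vy, 0), and likewise for
  acceleration. The identities right − left = vx and right·left = 0 hold
  bit-exactly per bin.
* **Translation invariance.** Positions are re-referenced to the first
  sample before any arithmetic, so every derivative is computed from
  position differences only. A session translated by an exactly
  representable constant therefore produces bit-identical velocity and
  acceleration components.
* **Coordinates.** x rightward, y upward, in the animal's frame.
  `camera_mirrored_x: true` flips x at load for camera-facing-animal data;
  it swaps the left/right components exactly and leaves up/down untouched.
* **Stimulation metrics.** Per stimulation train, distance is the
  displacement between the head position at train onset and at train
  termination; the speed series is the central-difference derivative of
  d(t) = |pos(t) − pos(onset)| inside the train, and peak speed its
  maximum.

## Two-step encoding analysis

For each unit and each of the eight kinematic variables:

1. **Lag scan.** Pearson r between the binned rate and the variable shifted
   by every integer lag in ±`max_lag_s` (default 0.5 s ⇒ ±16 bins). The
   window is a package choice — physiological leads are tens to a couple of
   hundred ms, so ±0.5 s is generous without admitting spurious far-lag
   maxima. We maximise |r|, not r: units that pause during movement couple
   negatively and must be found by the same scan. Ties prefer the smallest
   |lag|, then the negative (neural-activity-leading) lag, making the
   output deterministic. Positive lag = kinematics follows the neural
   signal. Masked bins are dropped pairwise at each lag (the overlap is
   recomputed per lag, nothing is imputed); lags with fewer than
   `min_overlap_bins` (default 100) jointly valid bins are skipped.
2. **Shifted Pearson.** r and the two-sided p from the t transform with
   n − 2 degrees of freedom at the winning alignment.

The unit's class is the variable with the largest |r| among those with
p < α (default 0.05); "uncorrelated" if none. The entire session enters the
correlation, inter-trial intervals included. No correction is made across
the eight variables — a deliberate replication of the classical per-variable
α procedure.

**Honest inference caveat.** The parametric p is computed at a lag selected
by maximising |r| over ~33 lags, and session-long series are autocorrelated;
both inflate significance. Truly uncoupled units are therefore classified by
chance fairly often under the default (with 8 variables, family-wise chance
classification approaches 1 − 0.95⁸ ≈ 34%, more with autocorrelation). The
`null: shuffle` configuration replaces the parametric p with a circular-shift
permutation p whose null statistic is the same max-|r|-over-lags, which
accounts for both effects; the default remains the classical procedure.

**Opponency.** For each axis, the opposite-direction r is evaluated at the
*preferred* direction's best lag. The sign argument is algebraic: the two
rectified halves of an axis are never jointly nonzero, so at a common
alignment cov(a, b) = −E[a]·E[b] < 0 whenever both directions occur — a unit
positively coupled to one direction must correlate negatively with the
other there. At the opposite component's own best-|r| lag the sign can
instead reflect bout sequencing (overshoot corrections, return movements),
which is why the summary pins the alignment.

**GABA-derivative test.** The GABA rate is differentiated by central
difference (the two one-sided edge bins are excluded from the correlation,
since their truncation error differs) and the result is lag-scanned against
the DA rate; a negative peak r is the mirror-image/disinhibition signature.

## Cell-type classification

Putative DA units: mean rate ≤ 12 Hz AND spike-width FWHM ≥ 0.5 ms
(`cell_rule`). The literature supports the qualitative rule (DA = slow,
wide) but no universal numeric cutoffs; both thresholds are configuration,
and the synthetic populations are generated well-separated so nothing
downstream depends on their exact values. Units without waveform metadata
are "unknown" and excluded from class comparisons. The classifier is
monotone: lowering the rate or widening the spike never flips DA → nonDA.

## Population statistics

* 2×2 chi-squares (lateralization; valence proportions) are Pearson's
  without the Yates continuity correction, matching how such statistics are
  conventionally reported for these designs; `yates=True` is available.
* The class-rate ANOVA is a one-way fixed-effects ANOVA over preferred
  directions (or direction × sign).
* Lag asymmetry: Welch t-test on |class lag| between positive and negative
  units, with per-sign mean ± SEM.
* The optogenetics ANOVA is a fixed-effects two-way ANOVA (genotype ×
  frequency, with interaction) on session-level mean summaries — a
  documented simplification of a repeated-measures design, since
  session-to-mouse assignment is not part of the data model. Degenerate
  inputs (zero response variance) return F = 0, p = 1 exactly.

## Synthetic sessions

### Cascade control model

Per axis, per step dt (default 1/300 s):

```
v        = K (p_ref − p)          # position controller, K = 8 /s
p       += dt v
v_sensed = v + noise              # sensor noise, mm/s (default 0)
e        = G (v_ref − v_sensed)   # DA gain G on the velocity error
p_ref   += dt (e − λ p_ref)       # leaky integrator, λ = 0.5 /s
```

The integrator leak acts on p_ref itself: with a zero velocity reference
the whole state then decays to rest (and with G = 0 the closed form
p_ref(t) = p_ref(0)·e^(−λt) is matched to O(dt)), which also returns the
animal toward its rest position after each movement bout without explicit
homing logic. A leak on the relative coordinate (p_ref − p) would instead
converge to a displaced plateau. Stability (forward Euler of the coupled
linear system, plus K·dt < 2 and λ·dt < 2) is checked before simulation.
With G = 0 no error ever enters the integrator and the position never
moves; larger G produces strictly faster movements for the same reference.
With `opponent_split` the signed error is phase-split into non-negative
direct/indirect channel signals with direct − indirect = e at every step.

### Task sessions

Trace conditioning: 100 ms tone; outcome drawn 1.9–2.1 s after tone offset;
inter-trial intervals uniform in 20–50 s (fast profile: 10 trials, 5–10 s
ITIs, for quick runs and CI-scale tests); schedules all-sucrose, AB, or
ABAB blocks. Movement is driven through the controller by raised-cosine
velocity-reference pulses (smooth and compactly supported, so acceleration
components are twice-differentiable): toward the spout (direction
(0.5, −0.866), peak 120 mm/s, 0.5 s) after the cue and after sucrose; away
from the spout after an air puff; an explicit return pulse 1.5 s after each
outcome (animals move to the spout and back — without returns the upward
components have almost no variance and vertical tuning is untestable);
spontaneous bouts at 0.15 Hz in uniformly random directions with peaks
50–140 mm/s. Per-bout direction jitter (s.d. 0.3 of the unit vector)
decorrelates the horizontal and vertical components across bouts. Tracking
is the simulated position sampled every 10 steps (exactly 30 frames/s) plus
0.15 mm measurement noise.

### Units

Intensity λ(t) = max(0, baseline + sign · gain · target(t + lag·Δ)): the
rate *anticipates* its kinematic target by the planted lag, matching the
convention that a positive recovered lag means neural activity leads
movement. Spikes are per-bin Poisson counts on a 1 ms grid with timestamps
uniform within bins — exact under any coarser rebinning. Gains are derived
from a dimensionless modulation depth m: gain = m·sqrt(baseline/Δ)/sd(target),
so the coupling term's s.d. is m times the Poisson count-noise s.d. at the
analysis bin width regardless of the target's units. Defaults m = 1.0
(positive units, baseline 5 Hz) and m = 1.4 (negative units, baseline
16 Hz) put session-wide |r| at the planted variable at ≈0.43–0.63 for
positive units on the fast profile; negative ("pause") units land lower
(|r| ≈ 0.15–0.2) because their modulation is clipped at zero rate — a real
constraint of pause coding, and their recovery remains reliable. Planted
leads: 0–1 bins for positive units, 4–6 bins (~120–180 ms) for negative
units. Waveform metadata is drawn class-conditionally (DA: FWHM
~N(1.1, 0.15) ms; GABA-like: ~N(0.25, 0.04) ms).

Cohorts allocate classes by largest remainder from a mix template shaped
like a typical nigral recording cohort (velocity:acceleration ≈ 66:31 among
classified, ~78% positive, a few uncorrelated units); horizontal-direction
units sit contralateral to their preferred direction with probability
`contralateral_bias` (default 0.75). Each cohort also carries paired
GABA/DA pseudo-units sharing the trajectory: the GABA unit codes −y
position (baseline 30 Hz), its partner codes vel_up, so the derivative of
the GABA rate mirrors the DA rate.

### Stimulation sessions

Trains of 1 s at the configured frequencies, inter-train intervals 9–12 s.
ChR2-genotype sessions receive a stimulus-locked velocity-reference pulse
(default peak 40 mm/s) in a random direction per train; control sessions
receive the trains with no coupling; both share the spontaneous-movement
background. For ANOVA calibration at scale, `sample_stim_summary_table`
draws session × frequency summaries directly (Gaussian, s.d. 2.5 mm/s
between sessions — consistent with per-train variability ~7 mm/s averaged
over ~8 trains, and the level at which a +2 mm/s genotype effect across 20
sessions is detectable with ~85% power); with zero effect it is an exact
null, used for the type-I calibration runs.

## What the generator does and does not emulate

It emulates: trial-locked and spontaneous movement bouts through a single
closed-loop controller, Poisson spiking tuned to rectified kinematics with
neural leads, cohort composition, lateralization bias, GABA/DA pairing, and
optogenetic movement induction. It does not emulate: spike sorting noise or
unit contamination, non-Poisson firing statistics (bursting, refractoriness),
nonstationary tuning, body-part-specific kinematics beyond a single tracked
point, z-axis movement, or history-dependent behaviour (satiety, learning).
Passing recovery tests therefore validates the analysis pipeline's
correctness and calibration on data that satisfy its assumptions; it cannot
certify performance on recordings that violate them.

## Problem sizes in the test suite and acceptance script

The suite and the acceptance script use the fast task profile (10 trials,
5–10 s ITIs, ~90 s sessions, ~3,000 analysis bins), a 100-unit cohort for
recovery, 50 seeded units each for the opponency and GABA-derivative
fractions, and 2,000 replicates for each type-I calibration. These sizes
give stable statistics (binomial s.e. < 0.5% at 2,000 replicates) while
keeping a full run around a minute.

## Known limitations

* The default significance is anti-conservative by construction (selection
  over lags; autocorrelation); use `null: shuffle` for calibrated p values.
* Lag estimates are quantised to 30 ms bins; sub-bin leads are not resolved.
* The controller is linear; it does not saturate, so extreme gain values
  produce unphysically fast movements rather than motor limits.
* The two-way stimulation ANOVA treats sessions as exchangeable units;
  mouse identity is not modelled.
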