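# kinencode

Movement-kinematics encoding analysis for single units recorded in the
substantia nigra of freely moving mice — plus a fully specified synthetic
session generator so the entire pipeline can be validated by parameter
recovery without any recorded data.

## The scientific problem

Dopaminergic (DA) neurons of the substantia nigra pars compacta fire phasic
bursts around behavioural events (cues, rewards), classically interpreted as
reward prediction errors. An alternative account holds that this activity
tracks the *kinematics* of the movements the animal makes at those moments.
Testing that account requires relating each unit's firing rate continuously
to movement, over whole sessions rather than around experimenter-chosen
events. `kinencode` implements that analysis for 2D head-tracking data:

1. **Kinematic decomposition.** Head position (x, y, mm, ~30 frames/s) is
   resampled to a 30 ms grid and differentiated to velocity
   v = (vx, vy) and acceleration a = (ax, ay). Each axis is split into
   rectified halves, giving eight directional variables:
   vel_up = max(vy, 0), vel_down = max(−vy, 0), vel_left, vel_right, and the
   four acceleration analogues. By construction
   vel_right − vel_left = vx and vel_right · vel_left = 0 per bin.
2. **Two-step classification.** For each (unit, variable) pair, the spike
   train is binned on the same grid and a cross-correlation over integer
   lags ℓ ∈ [−L, L] (default ±0.5 s) finds the lag ℓ* maximising |r|; a
   Pearson correlation at that alignment gives (r, p) with n − 2 degrees of
   freedom. A unit's class is the variable with the largest |r| among those
   with p < 0.05; its sign is sign(r). Positive lag means the neural signal
   leads movement. The whole session enters the correlation, inter-trial
   intervals included, so the classification is not tied to task events.
3. **Population statistics.** Class count tables, positive/negative
   proportions, opponency (a unit positively coupled to one direction
   correlates negatively with the opposite direction at the same
   alignment), hemisphere × preferred-direction lateralization chi-square,
   firing-rate ANOVAs across classes, burst-vs-pause lag asymmetry (Welch
   t), and a genotype × frequency two-way ANOVA for optogenetic
   stimulation sessions (peak speed, distance).
4. **GABA-derivative relationship.** Pars reticulata GABA output neurons
   carry position; DA neurons carry velocity. For simultaneously recorded
   pairs, the central-difference derivative of the GABA rate is correlated
   against the DA rate; a mirror-image (negative peak r) relationship is
   the disinhibition signature.

## The synthetic generator: cascade velocity→position control

Sessions are synthesised by a two-level negative-feedback hierarchy run per
axis in discrete time: a velocity comparator forms the error
e = G·(v_ref − v_sensed), where G is the dopaminergic gain; a leaky
integrator accumulates e into a position reference p_ref (the magnitude of
the integrator's input sets the rate of change of its output); a downstream
proportional controller moves at v = K·(p_ref − p). Task structure follows
trace conditioning: a 100 ms tone, outcome ~2 s after tone offset
(sucrose → movement toward the spout; air puff → away), 20–50 s
inter-trial intervals with spontaneous movement bouts, 50–150 trials.
Units are inhomogeneous-Poisson processes whose intensity couples to one
kinematic variable (or a position coordinate for GABA-like units) with a
known sign, gain and lead, so every analysis stage has ground truth.

## Worked example

```bash
kinencode simulate --seed 3 --n-units 12 --fast --out demo/
kinencode analyze demo/
kinencode recover demo/
```

`analyze` writes `demo/classifications.csv`, one row per unit:

```
unit_id,class_variable,direction,sign,best_lag_s,r,p
da_pair00,velocity,up,positive,0,0.593179670835,3.00840397155e-304
gaba00,velocity,up,positive,0.39,0.313577694652,7.67367124012e-74
...
```

`da_pair00` is a DA-like unit coupled to upward velocity: it is classified
as a positive velocity-up unit with r = 0.59 at lag 0, i.e. its firing rises
and falls with upward speed. `recover` compares all classifications with the
generator's ground truth:

```json
{
  "class_accuracy": 1.0,
  "sign_accuracy": 1.0,
  "median_lag_error_bins": 0.0,
  "n_units": 13,
  ...
}
```

Every kinematically coupled unit was assigned its planted variable and
sign, and the planted neural-lead lags were recovered with median error of
zero 30 ms bins. The library API mirrors the CLI
(`kinencode.analyze_session`, `kinencode.synthetic_data.generate_cohort`,
`kinencode.pipeline.score_recovery`).

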