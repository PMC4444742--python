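"""Synthetic sessions with known ground truth.

Everything the analysis pipeline consumes can be generated here from first
principles: a trace-conditioning task timeline (100 ms tone, outcome ~2 s
after tone offset, long inter-trial intervals), trajectories produced by the
cascade control model, kinematically tuned inhomogeneous-Poisson units,
position-coding GABA-like units paired with velocity-coding DA-like units,
and optogenetic stimulation sessions.  Every generator is a pure function of
its spec and a seeded ``numpy.random.Generator``, so each analysis stage is
testable by parameter recovery.

Spike generation draws per-bin Poisson counts at 1 ms resolution and places
timestamps uniformly within bins, which is exact under any coarser
rebinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..kinematics import COMPONENT_NAMES, decompose_components, component_parts
from ..session_io import SessionBundle, SessionEvents, TrackingSeries, UnitRecording
from .control_model import (ControlModelParams, ControlTrace,
                            raised_cosine_pulse, simulate_control_trajectory)

SPIKE_DT = 0.001  # s; resolution of the inhomogeneous-Poisson intensity
ANALYSIS_BIN = 0.030  # s; the analysis grid the planted lags refer to

TARGET_NAMES = COMPONENT_NAMES + ("x", "y")


@dataclass
class TaskSpec:
    """Trace-conditioning task layout and movement-bout statistics.

    Defaults reflect the standard task: 100 ms tone, outcome ~2 s after tone
    offset, 20-50 s inter-trial intervals, 50-150 trials per ~1 h session
    (60 here).  ``fast()`` gives a short profile (10 trials, 5-10 s ITI)
    for quick runs.
    """

    n_trials: int = 60
    tone_duration_s: float = 0.1
    outcome_delay_range_s: tuple[float, float] = (1.9, 2.1)
    iti_range_s: tuple[float, float] = (20.0, 50.0)
    outcome_schedule: str = "sucrose"  # "sucrose" | "AB" | "ABAB"
    spout_direction: tuple[float, float] = (0.5, -0.866)  # toward the spout
    cue_latency_s: float = 0.15
    outcome_latency_s: float = 0.1
    return_delay_s: float = 1.5   # movement back to rest after the outcome bout
    return_peak_frac: float = 0.9
    bout_peak_mms: float = 120.0
    bout_duration_s: float = 0.5
    spontaneous_bout_rate_hz: float = 0.15
    spont_peak_range_mms: tuple[float, float] = (50.0, 140.0)
    spont_duration_s: float = 0.4
    start_pad_s: float = 3.0
    end_pad_s: float = 3.0
    tracking_noise_sd_mm: float = 0.15

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials >= 1")
        for lo, hi in (self.outcome_delay_range_s, self.iti_range_s):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be ordered and positive")
        if self.tone_duration_s <= 0 or self.bout_duration_s <= 0:
            raise ValueError("durations must be > 0")
        if self.outcome_schedule not in ("sucrose", "AB", "ABAB"):
            raise ValueError("outcome_schedule must be sucrose|AB|ABAB")

    @classmethod
    def fast(cls, **overrides) -> "TaskSpec":
        kw = dict(n_trials=10, iti_range_s=(5.0, 10.0))
        kw.update(overrides)
        return cls(**kw)

    def outcome_types(self) -> list[str]:
        n = self.n_trials
        if self.outcome_schedule == "sucrose":
            return ["sucrose"] * n
        if self.outcome_schedule == "AB":
            half = n // 2
            return ["sucrose"] * half + ["airpuff"] * (n - half)
        block = max(n // 4, 1)  # ABAB
        out = []
        for i in range(n):
            out.append("sucrose" if (i // block) % 2 == 0 else "airpuff")
        return out


@dataclass
class TuningSpec:
    """Generative coupling of one synthetic unit to a kinematic target.

    Intensity: ``lambda(t) = max(0, baseline + sign * gain *
    target(t + lag_bins * 30 ms))`` — the unit's rate *anticipates* the
    kinematic signal by ``lag_bins`` analysis bins, matching the convention
    that a positive recovered lag means neural activity leads movement.
    ``target`` is one of the eight components, a position coordinate
    ("x"/"y"), or None for an uncoupled unit.
    """

    unit_id: str
    target: str | None
    sign: int = 1
    baseline_hz: float = 5.0
    gain: float = 0.0
    lag_bins: int = 0
    hemisphere: str = "unknown"
    cell_class: str = "DA"

    def __post_init__(self) -> None:
        if self.target is not None and self.target not in TARGET_NAMES:
            raise ValueError(f"unknown target {self.target!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +/-1")
        if self.baseline_hz < 0 or self.lag_bins < 0:
            raise ValueError("baseline >= 0 and lag_bins >= 0")


@dataclass
class SimulatedSession:
    """A generated session plus its ground truth."""

    tracking: TrackingSeries
    events: SessionEvents
    trace: ControlTrace
    targets: dict[str, np.ndarray]  # on the SPIKE_DT grid
    target_t: np.ndarray
    task: TaskSpec


def _schedule_events(task: TaskSpec, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, list[str], float]:
    cues, outcomes = [], []
    t = task.start_pad_s + float(rng.uniform(*task.iti_range_s)) * 0.2
    for _ in range(task.n_trials):
        cues.append(t)
        delay = float(rng.uniform(*task.outcome_delay_range_s))
        outcomes.append(t + task.tone_duration_s + delay)
        t = outcomes[-1] + float(rng.uniform(*task.iti_range_s))
    duration = outcomes[-1] + task.end_pad_s
    return np.array(cues), np.array(outcomes), task.outcome_types(), duration


def simulate_task_session(task: TaskSpec,
                          params: ControlModelParams | None = None,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> SimulatedSession:
    """Generate one task session through the cascade control model.

    Cue and outcome each trigger a raised-cosine velocity-reference pulse —
    toward the spout for cues and sucrose, away from it for air puffs — and
    spontaneous bouts in random directions occur throughout at the
    configured rate.  The integrator leak returns the animal toward its
    rest position after each bout.  Deterministic given the rng/seed.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    params = params or ControlModelParams()
    cues, outcomes, otypes, duration = _schedule_events(task, rng)
    dt = params.dt
    n = int(np.ceil(duration / dt))
    v_ref = np.zeros((n, 2))

    toward = np.asarray(task.spout_direction, dtype=float)
    toward = toward / np.hypot(*toward)

    def add_pulse(t0: float, direction: np.ndarray, peak: float, dur: float):
        jitter = direction + rng.normal(0.0, 0.3, size=2)  # trial-to-trial variability
        v_ref[:] += raised_cosine_pulse(n, dt, t0, dur, peak, tuple(jitter))

    for cue in cues:
        add_pulse(cue + task.cue_latency_s, toward, task.bout_peak_mms,
                  task.bout_duration_s)
    for out_t, ot in zip(outcomes, otypes):
        direction = toward if ot == "sucrose" else -toward
        add_pulse(out_t + task.outcome_latency_s, direction,
                  task.bout_peak_mms, task.bout_duration_s)
        # movement back toward the rest position after consuming/avoiding
        add_pulse(out_t + task.outcome_latency_s + task.return_delay_s,
                  -direction, task.return_peak_frac * task.bout_peak_mms,
                  task.bout_duration_s)

    n_spont = rng.poisson(task.spontaneous_bout_rate_hz * duration)
    for _ in range(n_spont):
        t0 = float(rng.uniform(0.0, duration - task.spont_duration_s))
        ang = float(rng.uniform(0.0, 2.0 * np.pi))
        peak = float(rng.uniform(*task.spont_peak_range_mms))
        add_pulse(t0, np.array([np.cos(ang), np.sin(ang)]), peak,
                  task.spont_duration_s)

    trace = simulate_control_trajectory(params, v_ref,
                                        rng=rng if params.sensor_noise_sd > 0 else None)

    stride = max(int(round((1.0 / 30.0) / dt)), 1)
    frame_idx = np.arange(0, n, stride)
    track_t = trace.t[frame_idx]
    noise = rng.normal(0.0, task.tracking_noise_sd_mm, size=(len(frame_idx), 2)) \
        if task.tracking_noise_sd_mm > 0 else np.zeros((len(frame_idx), 2))
    tracking = TrackingSeries(t=track_t,
                              x=trace.pos[frame_idx, 0] + noise[:, 0],
                              y=trace.pos[frame_idx, 1] + noise[:, 1],
                              frame_rate_nominal=round(1.0 / (stride * dt), 6))
    events = SessionEvents(cues, outcomes, otypes)

    target_t, targets = targets_from_trace(trace)
    return SimulatedSession(tracking=tracking, events=events, trace=trace,
                            targets=targets, target_t=target_t, task=task)


def targets_from_trace(trace: ControlTrace,
                       spike_dt: float = SPIKE_DT
                       ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Ground-truth coupling targets on the spike-resolution grid.

    Returns the eight rectified components plus the raw position coordinates,
    all derived from the controller's internal (noise-free) state.
    """
    t1 = np.arange(trace.t[0], trace.t[-1], spike_dt)
    vx = np.interp(t1, trace.t, trace.vel[:, 0])
    vy = np.interp(t1, trace.t, trace.vel[:, 1])
    ax = np.gradient(vx, spike_dt)
    ay = np.gradient(vy, spike_dt)
    targets = decompose_components(vx, vy, ax, ay)
    targets["x"] = np.interp(t1, trace.t, trace.pos[:, 0])
    targets["y"] = np.interp(t1, trace.t, trace.pos[:, 1])
    return t1, targets


def binned_truth(trace: ControlTrace, grid_t: np.ndarray) -> dict[str, np.ndarray]:
    """Internal velocity/position sampled at analysis-grid times."""
    out = {}
    for name, col in (("vx", 0), ("vy", 1)):
        out[name] = np.interp(grid_t, trace.t, trace.vel[:, col])
    for name, col in (("x", 0), ("y", 1)):
        out[name] = np.interp(grid_t, trace.t, trace.pos[:, col])
    return out


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

#: class-conditional waveform/rate metadata distributions
_FWHM_DIST = {"DA": (1.1, 0.15, 0.6), "GABA": (0.25, 0.04, 0.12),
              "unknown": (0.6, 0.1, 0.2)}


def generate_unit(spec: TuningSpec, session: SimulatedSession,
                  rng: np.random.Generator) -> UnitRecording:
    """Draw one inhomogeneous-Poisson unit coupled to its target.

    The intensity is the baseline plus the (sign-scaled) target advanced by
    the planted lag, floored at zero; counts are Poisson per 1 ms bin with
    timestamps uniform within bins.
    """
    t1 = session.target_t
    if spec.target is None:
        lam = np.full(len(t1), spec.baseline_hz)
    else:
        if spec.target not in session.targets:
            raise ValueError(f"target {spec.target!r} missing from session")
        target = session.targets[spec.target]
        if spec.target in ("x", "y"):
            # position coding is relative to the session-mean posture
            target = target - target.mean()
        shift = int(round(spec.lag_bins * ANALYSIS_BIN / SPIKE_DT))
        if shift > 0:  # rate at t reflects the target at t + lag (neural leads)
            target = np.concatenate([target[shift:],
                                     np.full(shift, target[-1])])
        lam = spec.baseline_hz + spec.sign * spec.gain * target
    lam = np.maximum(lam, 0.0)
    counts = rng.poisson(lam * SPIKE_DT)
    idx = np.nonzero(counts)[0]
    spikes = []
    for i in idx:
        spikes.append(t1[i] + rng.random(counts[i]) * SPIKE_DT)
    spike_times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)

    mu, sd, lo = _FWHM_DIST.get(spec.cell_class, _FWHM_DIST["unknown"])
    fwhm = float(max(rng.normal(mu, sd), lo))
    duration = t1[-1] - t1[0] + SPIKE_DT
    return UnitRecording(unit_id=spec.unit_id, spike_times=spike_times,
                         hemisphere=spec.hemisphere,
                         mean_rate=float(len(spike_times) / duration),
                         spike_width_fwhm=fwhm,
                         putative_class=spec.cell_class)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: default class-mix template (counts of velocity/acceleration units per
#: direction, negative-correlation fraction, and uncorrelated units) shaped
#: like a typical nigral recording cohort
DEFAULT_CLASS_MIX: dict[str, float] = {
    "vel_up": 18, "vel_down": 19, "vel_left": 13, "vel_right": 16,
    "acc_up": 9, "acc_down": 13, "acc_left": 4, "acc_right": 5,
    "uncorrelated": 9,
}
DEFAULT_POSITIVE_FRACTION = 0.78

#: planted modulation depth: the s.d. of the coupling term in units of the
#: Poisson count noise s.d. at the analysis bin width; these defaults put
#: session-wide |r| at the planted variable around 0.3-0.6 for positively
#: coupled units on the fast task profile (pause units are shallower — their
#: dynamic range is capped at zero rate)
DEFAULT_MODULATION = {"positive": 1.0, "negative": 1.4, "position": 1.0}
POSITIVE_BASELINE_HZ = 5.0
NEGATIVE_BASELINE_HZ = 16.0
POSITIVE_LAG_CHOICES = (0, 1)     # ~0-30 ms: bursts lead movement slightly
NEGATIVE_LAG_CHOICES = (4, 5, 6)  # ~120-180 ms: pauses lead by much more


def coupling_gain(baseline_hz: float, target_sd: float,
                  modulation: float) -> float:
    """Gain making the coupling term's s.d. ``modulation`` times the Poisson
    count-noise s.d. (``sqrt(baseline / bin_width)``) — a dimensionless
    signal-to-noise knob independent of the target's physical units."""
    if target_sd <= 0:
        raise ValueError("target has zero variance; cannot couple to it")
    return modulation * float(np.sqrt(baseline_hz / ANALYSIS_BIN)) / target_sd


def target_scales(session: SimulatedSession) -> dict[str, float]:
    """Standard deviation of every coupling target over the session."""
    return {name: float(np.std(series))
            for name, series in session.targets.items()}


def _largest_remainder(weights: dict[str, float], n: int) -> dict[str, int]:
    total = sum(weights.values())
    raw = {k: n * w / total for k, w in weights.items()}
    alloc = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(alloc.values())
    for k in sorted(raw, key=lambda k: raw[k] - alloc[k], reverse=True)[:short]:
        alloc[k] += 1
    return alloc


def assign_cohort_specs(n_units: int,
                        mix: dict[str, float] | None = None,
                        contralateral_bias: float = 0.75,
                        rng: np.random.Generator | None = None,
                        positive_fraction: float = DEFAULT_POSITIVE_FRACTION,
                        scales: dict[str, float] | None = None,
                        modulation: dict[str, float] | None = None
                        ) -> list[TuningSpec]:
    """Build the tuning specs for a cohort (no simulation involved).

    Class counts follow ``mix`` by largest-remainder allocation (exact
    composition, no sampling noise); signs are positive with
    ``positive_fraction``; horizontally tuned units sit in the hemisphere
    contralateral to their preferred direction with probability
    ``contralateral_bias``; all other units get a random hemisphere.
    ``scales`` (per-target s.d. from :func:`target_scales`) converts the
    modulation depths into physical gains; without it all gains are 0
    (labels-only cohorts, e.g. for calibration studies).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not 0.0 <= contralateral_bias <= 1.0:
        raise ValueError("contralateral_bias in [0, 1]")
    mix = mix or DEFAULT_CLASS_MIX
    modulation = modulation or DEFAULT_MODULATION
    alloc = _largest_remainder(mix, n_units)
    specs: list[TuningSpec] = []
    k = 0
    for target, count in alloc.items():
        for _ in range(count):
            unit_id = f"unit{k:03d}"
            k += 1
            if target == "uncorrelated":
                hemi = "left" if rng.random() < 0.5 else "right"
                specs.append(TuningSpec(unit_id, None, 1, POSITIVE_BASELINE_HZ,
                                        0.0, 0, hemi, "DA"))
                continue
            _, direction = component_parts(target)
            positive = rng.random() < positive_fraction
            sign = 1 if positive else -1
            lag = int(rng.choice(POSITIVE_LAG_CHOICES if positive
                                 else NEGATIVE_LAG_CHOICES))
            baseline = POSITIVE_BASELINE_HZ if positive else NEGATIVE_BASELINE_HZ
            gain = 0.0
            if scales is not None:
                gain = coupling_gain(baseline, scales[target],
                                     modulation["positive" if positive
                                                else "negative"])
            if direction in ("left", "right"):
                contra = "right" if direction == "left" else "left"
                ipsi = "left" if contra == "right" else "right"
                hemi = contra if rng.random() < contralateral_bias else ipsi
            else:
                hemi = "left" if rng.random() < 0.5 else "right"
            specs.append(TuningSpec(unit_id, target, sign, baseline, gain,
                                    lag, hemi, "DA"))
    return specs


def gaba_da_pair_specs(pair_idx: int, scales: dict[str, float] | None = None,
                       modulation: dict[str, float] | None = None
                       ) -> tuple[TuningSpec, TuningSpec]:
    """A position-coding GABA-like unit and its velocity-coding DA partner.

    The GABA unit carries -y position (its rate falls as the head rises), so
    the derivative of its rate mirrors the DA unit's upward-velocity signal.
    """
    modulation = modulation or DEFAULT_MODULATION
    gaba_baseline = 30.0
    g_pos = coupling_gain(gaba_baseline, scales["y"], modulation["position"]) \
        if scales else 0.0
    g_vel = coupling_gain(POSITIVE_BASELINE_HZ, scales["vel_up"],
                          modulation["positive"]) if scales else 0.0
    gaba = TuningSpec(f"gaba{pair_idx:02d}", "y", -1, gaba_baseline,
                      g_pos, 0, "left", "GABA")
    da = TuningSpec(f"da_pair{pair_idx:02d}", "vel_up", 1,
                    POSITIVE_BASELINE_HZ, g_vel, 0, "left", "DA")
    return gaba, da


def generate_cohort(n_units: int = 100,
                    mix: dict[str, float] | None = None,
                    contralateral_bias: float = 0.75,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    task: TaskSpec | None = None,
                    params: ControlModelParams | None = None,
                    n_gaba_pairs: int = 2,
                    modulation: dict[str, float] | None = None
                    ) -> tuple[SessionBundle, SimulatedSession, list[TuningSpec]]:
    """A full synthetic session with ``n_units`` ground-truth-labelled units.

    All units share one trajectory.  Paired GABA/DA pseudo-units for the
    derivative test are appended after the main cohort.  Returns the bundle,
    the simulated session (with internal traces) and the tuning specs.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    task = task or TaskSpec.fast()
    session = simulate_task_session(task, params, rng=rng)
    scales = target_scales(session)
    specs = assign_cohort_specs(n_units, mix, contralateral_bias, rng,
                                scales=scales, modulation=modulation)
    for i in range(n_gaba_pairs):
        specs.extend(gaba_da_pair_specs(i, scales, modulation))
    units = [generate_unit(s, session, rng) for s in specs]
    ground_truth = {s.unit_id: asdict(s) for s in specs}
    provenance = {"generator": "kinencode.synthetic_data.generate_cohort",
                  "seed": seed, "n_units": n_units,
                  "contralateral_bias": contralateral_bias,
                  "ground_truth": ground_truth}
    bundle = SessionBundle(session.tracking, session.events, units,
                           provenance=provenance)
    return bundle, session, specs


# ---------------------------------------------------------------------------
# optogenetic stimulation sessions
# ---------------------------------------------------------------------------

@dataclass
class StimSessionSpec:
    """Layout of one optogenetic stimulation session."""

    genotype: str = "chr2"  # "chr2" | "control"
    frequencies_hz: tuple[float, ...] = (11.0, 15.0, 25.0)
    n_trains_per_freq: int = 8
    train_duration_s: float = 1.0
    iti_range_s: tuple[float, float] = (9.0, 12.0)
    effect_peak_mms: float = 40.0  # stimulus-locked reference amplitude (ChR2)
    spontaneous_bout_rate_hz: float = 0.05
    start_pad_s: float = 3.0
    tracking_noise_sd_mm: float = 0.15


def generate_stim_session(spec: StimSessionSpec,
                          params: ControlModelParams | None = None,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None
                          ) -> tuple[TrackingSeries, list[tuple[float, float, float]], str]:
    """One stimulation session: tracking + non-overlapping trains + genotype.

    ChR2 sessions receive a stimulus-locked velocity-reference pulse in a
    random direction during each train; control sessions receive the trains
    (light only) with no movement coupling.  Both genotypes share the same
    spontaneous movement background.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    params = params or ControlModelParams()
    if spec.genotype not in ("chr2", "control"):
        raise ValueError("genotype must be 'chr2' or 'control'")
    freqs = []
    for f in spec.frequencies_hz:
        freqs.extend([f] * spec.n_trains_per_freq)
    rng.shuffle(freqs)
    trains = []
    t = spec.start_pad_s
    for f in freqs:
        trains.append((t, t + spec.train_duration_s, float(f)))
        t += spec.train_duration_s + float(rng.uniform(*spec.iti_range_s))
    duration = t + spec.start_pad_s
    dt = params.dt
    n = int(np.ceil(duration / dt))
    v_ref = np.zeros((n, 2))
    if spec.genotype == "chr2":
        for (on, off, _f) in trains:
            ang = float(rng.uniform(0, 2 * np.pi))
            v_ref += raised_cosine_pulse(n, dt, on, off - on,
                                         spec.effect_peak_mms,
                                         (np.cos(ang), np.sin(ang)))
    n_spont = rng.poisson(spec.spontaneous_bout_rate_hz * duration)
    for _ in range(n_spont):
        t0 = float(rng.uniform(0.0, duration - 0.4))
        ang = float(rng.uniform(0, 2 * np.pi))
        v_ref += raised_cosine_pulse(n, dt, t0, 0.4,
                                     float(rng.uniform(30.0, 80.0)),
                                     (np.cos(ang), np.sin(ang)))
    trace = simulate_control_trajectory(params, v_ref,
                                        rng=rng if params.sensor_noise_sd > 0 else None)
    stride = max(int(round((1.0 / 30.0) / dt)), 1)
    idx = np.arange(0, n, stride)
    noise = rng.normal(0.0, spec.tracking_noise_sd_mm, size=(len(idx), 2)) \
        if spec.tracking_noise_sd_mm > 0 else np.zeros((len(idx), 2))
    tracking = TrackingSeries(trace.t[idx],
                              trace.pos[idx, 0] + noise[:, 0],
                              trace.pos[idx, 1] + noise[:, 1],
                              frame_rate_nominal=round(1.0 / (stride * dt), 6))
    return tracking, trains, spec.genotype


def sample_stim_summary_table(n_sessions_per_genotype: int,
                              frequencies_hz: tuple[float, ...],
                              genotype_effect_mms: float,
                              rng: np.random.Generator,
                              base_peak_mms: float = 20.0,
                              base_distance_mm: float = 8.0,
                              noise_sd: float = 2.5):
    """Session-level peak-speed/distance summaries drawn directly.

    A lightweight sampler for calibrating the two-way ANOVA: each
    (session, frequency) cell gets independent Gaussian summaries, with the
    ChR2 genotype offset by ``genotype_effect_mms`` in peak speed (and
    proportionally in distance).  With effect 0 this is an exact null.
    """
    import pandas as pd

    rows = []
    for genotype in ("control", "chr2"):
        eff = genotype_effect_mms if genotype == "chr2" else 0.0
        for s in range(n_sessions_per_genotype):
            for f in frequencies_hz:
                rows.append({
                    "genotype": genotype, "session": f"{genotype}{s}",
                    "frequency": f,
                    "peak_speed": base_peak_mms + eff + rng.normal(0, noise_sd),
                    "distance": base_distance_mm + 0.4 * eff + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


def planted_class_table(specs: list[TuningSpec]):
    """The ClassTable implied by the planted tuning specs (perfect recovery)."""
    from ..population_stats import ClassTable, _empty_counts

    counts = _empty_counts()
    hemis = {}
    n_unc = n_pos = n_neg = 0
    for s in specs:
        if s.target is None or s.target in ("x", "y"):
            if s.target is None:
                n_unc += 1
            continue
        q, d = component_parts(s.target)
        counts.loc[q, d] += 1
        if s.sign > 0:
            n_pos += 1
        else:
            n_neg += 1
        if s.hemisphere not in hemis:
            hemis[s.hemisphere] = _empty_counts()
        hemis[s.hemisphere].loc[q, d] += 1
    return ClassTable(counts=counts, n_uncorrelated=n_unc, n_positive=n_pos,
                      n_negative=n_neg, hemisphere_counts=hemis)
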