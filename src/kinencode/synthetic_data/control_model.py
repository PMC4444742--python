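"""Hierarchical cascade controller used to synthesise movement trajectories.

The generator realises, per axis, a two-level negative-feedback hierarchy in
discrete time:

* a **velocity controller** ("striatal" level): a comparator forms the
  velocity error ``e = G * (v_ref - v_sensed)`` where ``G`` is the
  dopaminergic gain, and a leaky integrator ("nigral" level) accumulates the
  error into a position reference ``p_ref`` — the magnitude of the signal
  entering the integrator sets the rate of change of its output;
* a **position controller** (downstream of the basal ganglia): produces
  movement at a velocity proportional to the position error,
  ``v = K * (p_ref - p)``.

Per time step ``dt``::

    v        = K * (p_ref - p)
    p       += dt * v
    v_sensed = v + noise
    e        = G * (v_ref - v_sensed)
    p_ref   += dt * (e - leak * p_ref)

With ``G = 0`` no error ever enters the integrator and the position never
moves; with ``v_ref = 0`` and ``leak > 0`` all state decays back to rest;
larger ``G`` yields faster movements for the same reference — the gain
knob the dopamine signal is hypothesised to turn.

When ``opponent_split`` is on, the signed error is split into antiphase
direct/indirect channel signals (a phase splitter): ``direct = max(e, 0)``,
``indirect = max(-e, 0)``, with ``direct - indirect == e`` at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UnstableModelError(ValueError):
    """The discrete-time controller would be unstable for these parameters."""


@dataclass
class ControlModelParams:
    """Gains, leaks and step size of the cascade controller.

    da_gain : dimensionless gain on the velocity error (>= 0).
    integrator_leak : 1/s decay of the integrator state back to rest (>= 0).
    position_gain : 1/s proportional gain of the position controller (> 0).
    dt : simulation step, s.
    sensor_noise_sd : mm/s white noise on the sensed velocity.
    """

    da_gain: float = 1.0
    integrator_leak: float = 0.5
    position_gain: float = 8.0
    dt: float = 1.0 / 300.0
    sensor_noise_sd: float = 0.0
    opponent_split: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.da_gain < 0 or self.integrator_leak < 0:
            raise ValueError("gains and leaks must be >= 0")
        if self.position_gain <= 0:
            raise ValueError("position_gain must be > 0")
        self.check_stability()

    def check_stability(self) -> None:
        if self.position_gain * self.dt >= 2.0:
            raise UnstableModelError("require position_gain * dt < 2")
        if self.integrator_leak * self.dt >= 2.0:
            raise UnstableModelError("require integrator_leak * dt < 2")
        # forward-Euler stability of the coupled (p_ref, p) linear system
        gk = self.da_gain * self.position_gain
        A = np.array([[-(gk + self.integrator_leak), gk],
                      [self.position_gain, -self.position_gain]])
        lam = np.linalg.eigvals(np.eye(2) + self.dt * A)
        if np.any(np.abs(lam) > 1.0 + 1e-12):
            raise UnstableModelError(
                "coupled velocity/position loop unstable at this dt")


@dataclass
class ControlTrace:
    """State traces from one simulation (arrays indexed by step).

    ``pos``/``vel``/``p_ref``/``error`` have shape (n, 2) for the x and y
    axes; channel traces are present only with ``opponent_split``.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    p_ref: np.ndarray
    error: np.ndarray
    v_ref: np.ndarray
    direct: np.ndarray | None = None
    indirect: np.ndarray | None = None
    params: ControlModelParams = field(default_factory=ControlModelParams)


def simulate_control_trajectory(params: ControlModelParams,
                                v_ref: np.ndarray,
                                rng: np.random.Generator | None = None,
                                p0: tuple[float, float] = (0.0, 0.0),
                                p_ref0: tuple[float, float] = (0.0, 0.0)
                                ) -> ControlTrace:
    """Run the cascade controller for a given velocity-reference series.

    ``v_ref`` has shape (n, 2) (mm/s per axis per step).  Deterministic when
    ``sensor_noise_sd == 0``; otherwise ``rng`` is required.
    """
    params.check_stability()
    v_ref = np.atleast_2d(np.asarray(v_ref, dtype=float))
    if v_ref.shape[1] != 2:
        raise ValueError("v_ref must have shape (n, 2)")
    n = v_ref.shape[0]
    dt = params.dt
    G, K, lam = params.da_gain, params.position_gain, params.integrator_leak
    noisy = params.sensor_noise_sd > 0
    if noisy and rng is None:
        raise ValueError("sensor noise requires an rng")
    noise = (rng.normal(0.0, params.sensor_noise_sd, size=(n, 2))
             if noisy else None)

    pos = np.empty((n, 2))
    vel = np.empty((n, 2))
    p_ref_tr = np.empty((n, 2))
    err_tr = np.empty((n, 2))
    direct = np.empty((n, 2)) if params.opponent_split else None
    indirect = np.empty((n, 2)) if params.opponent_split else None

    p = np.array(p0, dtype=float)
    p_ref = np.array(p_ref0, dtype=float)
    for i in range(n):
        v = K * (p_ref - p)
        p = p + dt * v
        v_sensed = v + noise[i] if noisy else v
        e = G * (v_ref[i] - v_sensed)
        p_ref = p_ref + dt * (e - lam * p_ref)
        pos[i] = p
        vel[i] = v
        p_ref_tr[i] = p_ref
        err_tr[i] = e
        if params.opponent_split:
            direct[i] = np.maximum(e, 0.0)
            indirect[i] = np.maximum(-e, 0.0)

    t = dt * np.arange(1, n + 1)
    return ControlTrace(t=t, pos=pos, vel=vel, p_ref=p_ref_tr, error=err_tr,
                        v_ref=v_ref, direct=direct, indirect=indirect,
                        params=params)


def raised_cosine_pulse(n_steps: int, dt: float, t0: float, duration: float,
                        peak: float, direction: tuple[float, float]
                        ) -> np.ndarray:
    """A smooth, compactly supported velocity-reference pulse.

    Raised-cosine speed profile (twice differentiable at the edges, so the
    resulting acceleration components are well defined), scaled by a unit
    direction vector.
    """
    t = dt * np.arange(1, n_steps + 1)
    prof = np.zeros(n_steps)
    inside = (t >= t0) & (t <= t0 + duration)
    phase = (t[inside] - t0) / duration
    prof[inside] = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    d = np.asarray(direction, dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    return prof[:, None] * (d / norm)[None, :]
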