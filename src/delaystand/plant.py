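"""Robotic balance plant: linearized inverted pendulum with torque delay and virtual limits.

The plant integrates ``I*theta_ddot - mm*g*L*theta = T`` exactly under a
zero-order hold on the applied torque.  Internally all angles are radians
(the linearized gravity term requires it); angles cross the public boundary
in degrees.  Positive theta is an anterior lean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

DEG = math.pi / 180.0

__all__ = [
    "PendulumParams",
    "LimitConfig",
    "DelayLine",
    "PlantState",
    "step_pendulum",
    "limit_torque",
    "fit_predictor",
    "predict_forward",
]


@dataclass(frozen=True)
class PendulumParams:
    """Physical parameters of the simulated standing body.

    The effective (moving) mass is 0.971 of total mass; the inertia about
    the ankles is ``mm * L**2``.
    """

    m: float = 75.0
    L: float = 1.0
    g: float = 9.81
    fs: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("m", "L", "g", "fs"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")
        if self.fs < 100:
            raise ValueError(f"sample rate fs must be >= 100 Hz, got {self.fs}")

    @property
    def mm(self) -> float:
        """Effective moving mass (kg)."""
        return 0.971 * self.m

    @property
    def inertia(self) -> float:
        """Moment of inertia about the ankles (kg m^2)."""
        return self.mm * self.L**2

    @property
    def toppling_coeff(self) -> float:
        """Gravitational stiffness mm*g*L (N m / rad)."""
        return self.mm * self.g * self.L

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def zoh_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact discrete update (Ad, Bd) of the 2-state system for one dt.

        Closed form of the matrix exponential for A = [[0, 1], [w^2, 0]],
        B = [0, 1/I]; w^2 = g/L since I = mm*L^2.
        """
        w = math.sqrt(self.g / self.L)
        dt = self.dt
        ch, sh = math.cosh(w * dt), math.sinh(w * dt)
        ad = np.array([[ch, sh / w], [w * sh, ch]])
        inv_i = 1.0 / self.inertia
        bd = np.array([(ch - 1.0) * inv_i / w**2, sh * inv_i / w])
        return ad, bd


@dataclass(frozen=True)
class LimitConfig:
    """Virtual angular limits and supportive-torque mechanics (degrees at the boundary)."""

    anterior_limit: float = 6.0
    posterior_limit: float = -3.0
    ramp_range: float = 1.0
    support_threshold_torque: float | None = None
    damping_coeff: float | None = None

    def __post_init__(self) -> None:
        if not (self.anterior_limit > 0 > self.posterior_limit):
            raise ValueError(
                "limits must satisfy anterior_limit > 0 > posterior_limit, got "
                f"{self.anterior_limit}, {self.posterior_limit}"
            )
        if self.ramp_range <= 0:
            raise ValueError(f"ramp_range must be > 0, got {self.ramp_range}")
        if self.support_threshold_torque is not None and self.support_threshold_torque <= 0:
            raise ValueError("support_threshold_torque must be > 0")

    def resolved(self, params: PendulumParams) -> "LimitConfig":
        """Fill defaults that depend on the pendulum parameters.

        The supportive-torque threshold defaults to the gravitational
        toppling torque at one ramp-range beyond the larger limit, i.e. the
        torque needed to passively hold the body there.  The damping
        coefficient defaults to the critical-damping scale 2*sqrt(I*mm*g*L).
        """
        support = self.support_threshold_torque
        if support is None:
            worst = max(self.anterior_limit, -self.posterior_limit) + self.ramp_range
            support = params.toppling_coeff * math.sin(worst * DEG)
        damping = self.damping_coeff
        if damping is None:
            damping = 2.0 * math.sqrt(params.inertia * params.toppling_coeff)
        return replace(self, support_threshold_torque=support, damping_coeff=damping)


@dataclass
class PlantState:
    """Instantaneous plant state; theta in radians, positive = anterior lean."""

    theta: float = 0.0
    theta_dot: float = 0.0
    time: float = 0.0
    limit_engaged: bool = False

    @property
    def theta_deg(self) -> float:
        return self.theta / DEG

    @property
    def theta_dot_dps(self) -> float:
        return self.theta_dot / DEG


class DelayLine:
    """Ring buffer of past torque samples; reads before t=delay return the hold value."""

    def __init__(self, capacity_ms: float = 1000.0, fs: float = 2000.0, hold_value: float = 0.0):
        if capacity_ms < 500:
            raise ValueError(f"capacity must be >= 500 ms, got {capacity_ms}")
        self.fs = float(fs)
        self.capacity_ms = float(capacity_ms)
        self._n = int(round(capacity_ms * fs / 1000.0)) + 1
        self._hold = float(hold_value)
        self._buf = np.full(self._n, self._hold)
        self._i = 0  # number of samples pushed

    def push(self, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError(f"torque pushed into delay line is not finite: {value!r}")
        self._buf[self._i % self._n] = value
        self._i += 1

    def delay_samples(self, delay_ms: float) -> int:
        d = int(round(delay_ms * self.fs / 1000.0))
        if delay_ms < 0 or delay_ms > self.capacity_ms:
            raise ValueError(
                f"requested delay {delay_ms} ms outside line capacity [0, {self.capacity_ms}] ms"
            )
        return d

    def read(self, delay_ms: float) -> float:
        """Torque recorded ``delay_ms`` ago (relative to the latest pushed sample)."""
        d = self.delay_samples(delay_ms)
        j = self._i - 1 - d
        if j < 0:
            return self._hold  # before t = delay: pre-trial hold (zero net torque)
        return float(self._buf[j % self._n])


def delayed_torque(line: DelayLine, delay_ms: float) -> float:
    """Functional wrapper over :meth:`DelayLine.read`."""
    return line.read(delay_ms)


def step_pendulum(state: PlantState, torque: float, params: PendulumParams,
                  _zoh: tuple[np.ndarray, np.ndarray] | None = None) -> PlantState:
    """Advance the linear pendulum one sample under a zero-order-hold torque."""
    if not np.isfinite(torque):
        raise ValueError(f"channel 'torque' is not finite: {torque!r}")
    if not (np.isfinite(state.theta) and np.isfinite(state.theta_dot)):
        raise ValueError(
            f"channel 'theta/theta_dot' is not finite: ({state.theta!r}, {state.theta_dot!r})"
        )
    ad, bd = params.zoh_matrices() if _zoh is None else _zoh
    th = ad[0, 0] * state.theta + ad[0, 1] * state.theta_dot + bd[0] * torque
    thd = ad[1, 0] * state.theta + ad[1, 1] * state.theta_dot + bd[1] * torque
    return PlantState(theta=th, theta_dot=thd, time=state.time + params.dt,
                      limit_engaged=state.limit_engaged)


def limit_torque(state: PlantState, cfg: LimitConfig) -> float:
    """Supportive/restoring torque from the virtual limits; zero inside them.

    Beyond a limit the torque ramps linearly from 0 at the limit to the
    support threshold at ``ramp_range`` beyond; a damping term opposes
    further outward velocity only while beyond the limit.
    """
    if cfg.support_threshold_torque is None or cfg.damping_coeff is None:
        raise ValueError("LimitConfig must be resolved (support/damping set) before use")
    theta_deg = state.theta / DEG
    if cfg.posterior_limit <= theta_deg <= cfg.anterior_limit:
        return 0.0
    # wall stiffness beyond the secondary limit: the simulated stiffness keeps
    # growing so no bounded ankle torque can rotate the body further
    wall_gain = 50.0
    if theta_deg > cfg.anterior_limit:
        exc = theta_deg - cfg.anterior_limit
        frac = min(exc / cfg.ramp_range, 1.0)
        t = -cfg.support_threshold_torque * frac
        if exc > cfg.ramp_range:
            t -= wall_gain * cfg.support_threshold_torque * (exc - cfg.ramp_range) / cfg.ramp_range
        if state.theta_dot > 0:  # moving further anterior
            t -= cfg.damping_coeff * state.theta_dot
        return t
    exc = cfg.posterior_limit - theta_deg
    frac = min(exc / cfg.ramp_range, 1.0)
    t = cfg.support_threshold_torque * frac
    if exc > cfg.ramp_range:
        t += wall_gain * cfg.support_threshold_torque * (exc - cfg.ramp_range) / cfg.ramp_range
    if state.theta_dot < 0:
        t -= cfg.damping_coeff * state.theta_dot
    return t


def step_with_limits(state: PlantState, torque: float, params: PendulumParams,
                     cfg: LimitConfig,
                     _zoh: tuple[np.ndarray, np.ndarray] | None = None) -> PlantState:
    """One plant step with limit mechanics: supportive/damping torque plus a
    kinematic stop at the secondary limits (limit + ramp_range).

    The stop removes any residual outward motion the wall torque could not
    absorb within the sample, so no bounded ankle torque can push the body
    more than one sample's travel beyond the secondary limits.
    """
    total = torque + limit_torque(state, cfg)
    new = step_pendulum(state, total, params, _zoh=_zoh)
    ant2 = (cfg.anterior_limit + cfg.ramp_range) * DEG
    post2 = (cfg.posterior_limit - cfg.ramp_range) * DEG
    if new.theta > ant2:
        new.theta = ant2
        new.theta_dot = min(new.theta_dot, 0.0)
        new.limit_engaged = True
    elif new.theta < post2:
        new.theta = post2
        new.theta_dot = max(new.theta_dot, 0.0)
        new.limit_engaged = True
    else:
        new.limit_engaged = not (
            cfg.posterior_limit * DEG <= new.theta <= cfg.anterior_limit * DEG
        )
    return new


def fit_predictor(theta: np.ndarray, horizon_samples: int, n_points: int = 6) -> np.ndarray:
    """Least-squares coefficients predicting theta[k + horizon] from the last 6 samples."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or theta.size < n_points + horizon_samples + 1:
        raise ValueError("training series too short for the requested horizon")
    n = theta.size - n_points - horizon_samples + 1
    idx = np.arange(n_points)[None, :] + np.arange(n)[:, None]
    x = theta[idx]
    y = theta[np.arange(n) + n_points - 1 + horizon_samples]
    coeffs, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coeffs


def predict_forward(samples: np.ndarray, coeffs: np.ndarray) -> float:
    """Linear combination of the last 6 angle samples with previously fit coefficients."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 6:
        raise ValueError(f"insufficient history: need 6 samples, got {samples.size}")
    if not np.all(np.isfinite(samples)):
        raise ValueError("channel 'theta' history contains non-finite samples")
    return float(np.dot(samples[-6:], np.asarray(coeffs, dtype=float)))
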