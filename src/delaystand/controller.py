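"""Delayed proportional-derivative balance controller closing the loop around the plant.

The controller is a stand-in for the human: it senses body angle through an
intrinsic sensorimotor delay (default 120 ms), commands ankle torque, and the
commanded torque reaches the plant after the motor delay (20 ms) plus any
imposed delay.  Torque noise (low-pass filtered Gaussian) drives sway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .plant import DEG, LimitConfig, PendulumParams, PlantState, limit_torque
from .interface.trialio import TrialRecord

__all__ = [
    "ControllerParams",
    "ClosedLoopResult",
    "pd_torque",
    "run_closed_loop",
    "retune_gains",
    "find_stability_margin",
]

MOTOR_DELAY_MS = 20.0


@dataclass(frozen=True)
class ControllerParams:
    kp: float = 786.0            # N m / rad (~1.1 * mm*g*L for the default plant)
    kd: float = 296.0            # N m s / rad (maximizes delay tolerance)
    intrinsic_delay_ms: float = 120.0
    noise_std: float = 1.0       # N m, std of the filtered torque noise
    noise_bandwidth: float = 2.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intrinsic_delay_ms < 0:
            raise ValueError("intrinsic_delay_ms must be >= 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")

    def check_stabilizable(self, params: PendulumParams) -> None:
        if self.kp <= params.toppling_coeff:
            warnings.warn(
                f"kp={self.kp} <= mm*g*L={params.toppling_coeff:.1f}: "
                "the loop cannot stabilize the inverted pendulum",
                stacklevel=2,
            )


@dataclass
class ClosedLoopResult:
    trial: TrialRecord
    limit_crossings: int
    diverged: bool


def pd_torque(theta_delayed: float, theta_dot_delayed: float,
              params: ControllerParams, noise: float = 0.0) -> float:
    """Torque command from delayed state feedback: -kp*theta - kd*theta_dot + noise."""
    return -params.kp * theta_delayed - params.kd * theta_dot_delayed + noise


def _torque_noise(n: int, fs: float, params: ControllerParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Seeded Gaussian noise, causally low-pass filtered and rescaled to noise_std."""
    if params.noise_std == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if params.noise_bandwidth and params.noise_bandwidth < fs / 2:
        sos = sps.butter(2, params.noise_bandwidth, fs=fs, output="sos")
        white = sps.sosfilt(sos, white)
    s = white.std()
    if s > 0:
        white = white * (params.noise_std / s)
    return white


def _schedule_to_samples(delay_schedule, n: int, fs: float) -> np.ndarray:
    """Piecewise-constant imposed delay (ms) per sample from (time_s, delay_ms) pairs."""
    sched = sorted(delay_schedule, key=lambda p: p[0])
    if not sched or sched[0][0] > 0:
        raise ValueError("delay schedule must cover t=0 (configuration error: schedule gap)")
    out = np.empty(n)
    times = np.arange(n) / fs
    starts = np.array([p[0] for p in sched])
    vals = np.array([float(p[1]) for p in sched])
    idx = np.searchsorted(starts, times, side="right") - 1
    out[:] = vals[idx]
    return out


def run_closed_loop(plant_params: PendulumParams, limits: LimitConfig,
                    ctrl: ControllerParams, delay_schedule, duration_s: float,
                    seed: int | None = None) -> ClosedLoopResult:
    """Simulate the delayed-feedback standing loop for ``duration_s`` seconds.

    ``delay_schedule`` is an int/float (constant imposed delay in ms) or a
    sequence of (onset_s, delay_ms) pairs covering [0, duration].  The total
    loop delay is intrinsic (sensing) + motor (20 ms) + imposed (actuation).
    Returns a TrialRecord with channels time, theta, theta_dot, torque, delay.
    """
    ctrl.check_stabilizable(plant_params)
    fs = plant_params.fs
    n = int(round(duration_s * fs))
    if np.isscalar(delay_schedule):
        delay_schedule = [(0.0, float(delay_schedule))]
    imposed = _schedule_to_samples(delay_schedule, n, fs)
    lim = limits.resolved(plant_params)
    rng = np.random.default_rng(ctrl.seed if seed is None else seed)
    noise = _torque_noise(n, fs, ctrl, rng)
    zoh = plant_params.zoh_matrices()

    d_sense = int(round(ctrl.intrinsic_delay_ms * fs / 1000.0))
    d_act = np.rint((MOTOR_DELAY_MS + imposed) * fs / 1000.0).astype(np.int64)

    theta = np.zeros(n)
    theta_dot = np.zeros(n)
    torque_cmd = np.zeros(n)
    state = PlantState()
    ant = lim.anterior_limit * DEG
    post = lim.posterior_limit * DEG
    ant2 = (lim.anterior_limit + lim.ramp_range) * DEG
    post2 = (lim.posterior_limit - lim.ramp_range) * DEG
    crossings = 0
    beyond_prev = False
    beyond_count = 0
    ad00, ad01 = zoh[0][0, 0], zoh[0][0, 1]
    ad10, ad11 = zoh[0][1, 0], zoh[0][1, 1]
    bd0, bd1 = zoh[1][0], zoh[1][1]
    th, thd = 0.0, 0.0
    for i in range(n):
        j = i - d_sense
        if j >= 0:
            s_th, s_thd = theta[j], theta_dot[j]
        else:
            s_th = s_thd = 0.0
        cmd = -ctrl.kp * s_th - ctrl.kd * s_thd + noise[i]
        torque_cmd[i] = cmd
        k = i - d_act[i]
        applied = torque_cmd[k] if k >= 0 else 0.0
        state.theta, state.theta_dot = th, thd
        t_lim = limit_torque(state, lim)
        total = applied + t_lim
        if not math.isfinite(total):
            raise FloatingPointError(f"non-finite torque at sample {i}")
        th_new = ad00 * th + ad01 * thd + bd0 * total
        thd_new = ad10 * th + ad11 * thd + bd1 * total
        th, thd = th_new, thd_new
        # kinematic stop at the secondary limits (see plant.step_with_limits)
        if th > ant2:
            th = ant2
            thd = min(thd, 0.0)
        elif th < post2:
            th = post2
            thd = max(thd, 0.0)
        theta[i] = th
        theta_dot[i] = thd
        beyond = th > ant or th < post
        if beyond and not beyond_prev:
            crossings += 1
        if beyond:
            beyond_count += 1
        beyond_prev = beyond

    diverged = beyond_count / n > 0.3
    trial = TrialRecord(
        fs=fs,
        time_s=np.arange(n) / fs,
        theta_deg=theta / DEG,
        theta_dot_dps=theta_dot / DEG,
        torque_nm=torque_cmd,
        delay_ms=imposed,
        meta={
            "kind": "closed_loop",
            "kp": ctrl.kp,
            "kd": ctrl.kd,
            "intrinsic_delay_ms": ctrl.intrinsic_delay_ms,
            "noise_std": ctrl.noise_std,
            "seed": int(ctrl.seed if seed is None else seed),
            "limit_crossings": crossings,
        },
    )
    return ClosedLoopResult(trial=trial, limit_crossings=crossings, diverged=diverged)


def _sway_objective(plant_params, limits, ctrl, imposed_delay_ms, duration_s, seeds):
    var = 0.0
    any_diverged = False
    for s in seeds:
        res = run_closed_loop(plant_params, limits, ctrl, imposed_delay_ms,
                              duration_s, seed=s)
        v = float(np.var(res.trial.theta_dot_dps, ddof=1))
        if res.diverged:
            any_diverged = True
            v += 1e6
        var += v
    return var / len(seeds), any_diverged


def retune_gains(plant_params: PendulumParams, limits: LimitConfig,
                 ctrl: ControllerParams, imposed_delay_ms: float,
                 kp_grid=None, kd_grid=None, duration_s: float = 30.0,
                 seeds=(0, 1)) -> tuple[ControllerParams, float, bool]:
    """Coordinate grid search over (kp, kd) minimizing sway-velocity variance.

    The current gains are always included in the grid, so the retuned
    objective never exceeds the starting one on the same seeds.  Returns
    (params, objective, diverged_flag); the flag marks a best-effort result
    when no candidate avoided divergence.
    """
    mgl = plant_params.toppling_coeff
    if kp_grid is None:
        kp_grid = mgl * np.array([1.3, 1.7, 2.2, 2.8, 3.5])
    if kd_grid is None:
        kd_grid = mgl * np.array([0.2, 0.35, 0.5, 0.7, 1.0])
    candidates = [(float(kp), float(kd)) for kp in kp_grid for kd in kd_grid]
    if (ctrl.kp, ctrl.kd) not in candidates:
        candidates.append((ctrl.kp, ctrl.kd))
    best = None
    for kp, kd in candidates:
        cand = ControllerParams(kp=kp, kd=kd,
                                intrinsic_delay_ms=ctrl.intrinsic_delay_ms,
                                noise_std=ctrl.noise_std,
                                noise_bandwidth=ctrl.noise_bandwidth, seed=ctrl.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obj, div = _sway_objective(plant_params, limits, cand, imposed_delay_ms,
                                       duration_s, seeds)
        if best is None or obj < best[1]:
            best = (cand, obj, div)
    return best


def find_stability_margin(plant_params: PendulumParams, limits: LimitConfig,
                          ctrl: ControllerParams, lo_ms: float = 0.0,
                          hi_ms: float = 480.0, tol_ms: float = 10.0,
                          duration_s: float = 20.0) -> float:
    """Largest imposed delay (ms) that does not diverge, found by bisection."""
    quiet = ControllerParams(kp=ctrl.kp, kd=ctrl.kd,
                             intrinsic_delay_ms=ctrl.intrinsic_delay_ms,
                             noise_std=0.0, seed=ctrl.seed)

    def diverges(d):
        # perturb slightly off equilibrium so instability expresses itself
        fs = plant_params.fs
        n = int(round(duration_s * fs))
        res = _run_perturbed(plant_params, limits, quiet, d, duration_s)
        return res

    while hi_ms - lo_ms > tol_ms:
        mid = 0.5 * (lo_ms + hi_ms)
        if diverges(mid):
            hi_ms = mid
        else:
            lo_ms = mid
    return lo_ms


def _run_perturbed(plant_params, limits, ctrl, imposed_delay_ms, duration_s):
    """True if an initial 0.2 deg perturbation grows rather than decays."""
    fs = plant_params.fs
    n = int(round(duration_s * fs))
    lim = limits.resolved(plant_params)
    zoh = plant_params.zoh_matrices()
    ad, bd = zoh
    d_sense = int(round(ctrl.intrinsic_delay_ms * fs / 1000.0))
    d_act = int(round((MOTOR_DELAY_MS + imposed_delay_ms) * fs / 1000.0))
    theta = np.zeros(n + 1)
    theta_dot = np.zeros(n + 1)
    torque = np.zeros(n + 1)
    theta[0] = 0.2 * DEG
    for i in range(n):
        j = i - d_sense
        s_th = theta[j] if j >= 0 else 0.0
        s_thd = theta_dot[j] if j >= 0 else 0.0
        torque[i] = -ctrl.kp * s_th - ctrl.kd * s_thd
        k = i - d_act
        applied = torque[k] if k >= 0 else 0.0
        theta[i + 1] = ad[0, 0] * theta[i] + ad[0, 1] * theta_dot[i] + bd[0] * applied
        theta_dot[i + 1] = ad[1, 0] * theta[i] + ad[1, 1] * theta_dot[i] + bd[1] * applied
        if abs(theta[i + 1]) > 20 * DEG:
            return True
    tail = np.abs(theta[int(0.75 * n):]).max()
    return tail > 0.2 * DEG
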