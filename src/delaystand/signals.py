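"""Synthetic-data hub: vestibular stimuli, coupled EMG envelopes, button presses,
and session designs for every experiment, so all analyses run without downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.special import ndtr

from .interface.trialio import TrialRecord

__all__ = [
    "EVSConfig",
    "VestibularCoupling",
    "PerceptTruth",
    "DelayPeriod",
    "SessionDesign",
    "generate_evs",
    "biphasic_kernel",
    "generate_emg",
    "generate_button",
    "make_session",
    "synthesize_experiment",
    "EXPERIMENT_TAGS",
]

EXPERIMENT_TAGS = ("exp1", "exp2-vest", "exp2-percept", "exp3", "training")

EXP1_DELAYS_MS = (20, 100, 200, 300, 400, 500)
EXP2_VEST_DELAYS_MS = (20, 100, 200, 300, 400, 500)
EXP2_PERCEPT_DELAYS_MS = (50, 100, 150, 200, 250, 300, 350)
BASELINE_DELAY_MS = 20.0


@dataclass(frozen=True)
class EVSConfig:
    """Band-limited stochastic vestibular stimulus configuration."""

    duration_s: float
    fs: float = 2000.0
    band_hi: float = 25.0
    target_rms: float = 1.38
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_hi < self.fs / 2:
            raise ValueError(f"band_hi must lie in (0, fs/2), got {self.band_hi}")
        if self.target_rms < 0:
            raise ValueError("target_rms must be >= 0")


def generate_evs(cfg: EVSConfig) -> np.ndarray:
    """Seeded white noise, zero-phase low-passed to ``band_hi``, rescaled to exact RMS."""
    n = int(round(cfg.duration_s * cfg.fs))
    sos = sps.butter(8, cfg.band_hi, fs=cfg.fs, output="sos")
    # sosfiltfilt needs enough samples for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if n <= padlen:
        raise ValueError(
            f"duration*fs = {n} samples is shorter than the filter warm-up ({padlen})"
        )
    rng = np.random.default_rng(cfg.seed)
    x = rng.standard_normal(n)
    x = sps.sosfiltfilt(sos, x)
    rms = math.sqrt(np.mean(x**2))
    if cfg.target_rms == 0 or rms == 0:
        return np.zeros(n)
    return x * (cfg.target_rms / rms)


def biphasic_kernel(fs: float, short_latency_s: float = 0.060,
                    medium_latency_s: float = 0.100,
                    short_width_s: float = 0.015, medium_width_s: float = 0.025,
                    length_s: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Difference-of-Gaussians impulse response with opposite-signed lobes.

    Short-latency lobe is negative, medium-latency positive; peak magnitude
    normalized to 1.  Returns (lags_s, kernel).
    """
    lags = np.arange(int(round(length_s * fs))) / fs
    k = (-np.exp(-0.5 * ((lags - short_latency_s) / short_width_s) ** 2)
         + np.exp(-0.5 * ((lags - medium_latency_s) / medium_width_s) ** 2))
    return lags, k / np.abs(k).max()


@dataclass
class VestibularCoupling:
    """EMG response kernel to the vestibular stimulus, with a schedulable gain."""

    fs: float = 2000.0
    short_latency_s: float = 0.060
    medium_latency_s: float = 0.100
    amplitude: float = 1.0
    gain_schedule: Callable[[np.ndarray], np.ndarray] | None = None
    kernel: np.ndarray = field(default=None, repr=False)
    lags_s: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kernel is None:
            self.lags_s, self.kernel = biphasic_kernel(
                self.fs, self.short_latency_s, self.medium_latency_s)

    def gains(self, t: np.ndarray) -> np.ndarray:
        if self.gain_schedule is None:
            return np.ones_like(t)
        g = np.asarray(self.gain_schedule(t), dtype=float)
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("gain_schedule must stay within [0, 1]")
        return g


def generate_emg(trial: TrialRecord, evs: np.ndarray, coupling: VestibularCoupling,
                 tonic: float = 1.0, torque_gain: float = 0.0,
                 noise_std: float = 0.1, seed: int = 0,
                 coupling_rms: float = 0.3) -> np.ndarray:
    """Rectified EMG envelope with a scheduled vestibular-coupled component.

    envelope = max(0, tonic + torque_gain*torque + gain(t)*(kernel * evs) + noise)

    The coupled component is rescaled so its (pre-schedule) RMS equals
    ``coupling.amplitude * coupling_rms``, keeping the envelope clear of the
    rectification floor at the default tonic level.
    """
    n = len(trial)
    evs = np.asarray(evs, dtype=float)
    if len(evs) != n:
        raise ValueError(
            f"channel length mismatch: evs has {len(evs)} samples, trial has {n}"
        )
    t = trial.time_s
    coupled = sps.fftconvolve(evs, coupling.kernel)[:n]
    raw_rms = math.sqrt(np.mean(coupled**2))
    if raw_rms > 0:
        coupled *= coupling.amplitude * coupling_rms / raw_rms
    coupled *= coupling.gains(t)
    drive = np.zeros(n)
    if torque_gain and trial.torque_nm is not None:
        drive = torque_gain * trial.torque_nm
    rng = np.random.default_rng(seed)
    noise = noise_std * rng.standard_normal(n) if noise_std else 0.0
    env = tonic + drive + coupled + noise
    return np.maximum(env, 0.0)


@dataclass(frozen=True)
class PerceptTruth:
    """Generative ground truth for the detection (button) behavior."""

    mu_s: float = 0.15
    sigma_s: float = 0.05
    delta: float = 0.02
    latency_log_mean: float = math.log(2.5)
    latency_log_sd: float = 0.45
    latency_floor_s: float = 0.5
    false_press_rate_per_min: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.delta <= 0.05:
            raise ValueError("delta must lie in [0, 0.05]")
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be > 0")

    def detect_probability(self, delay_s: float | np.ndarray) -> np.ndarray:
        x = np.asarray(delay_s, dtype=float)
        return self.delta / 2 + (1 - self.delta) * ndtr((x - self.mu_s) / self.sigma_s)


@dataclass(frozen=True)
class DelayPeriod:
    onset_s: float
    delay_ms: float
    duration_s: float


@dataclass
class SessionDesign:
    """Per-participant, per-trial delay-period schedule for one experiment."""

    experiment: str
    #: participants -> trials -> list of DelayPeriod
    participants: list[list[list[DelayPeriod]]]
    trial_duration_s: float
    baseline_delay_ms: float = BASELINE_DELAY_MS

    def all_periods(self) -> list[DelayPeriod]:
        return [p for pp in self.participants for trial in pp for p in trial]

    def n_periods(self) -> int:
        return len(self.all_periods())

    def trial_schedule(self, participant: int, trial: int) -> list[tuple[float, float]]:
        """(onset_s, delay_ms) pairs covering [0, trial_duration] for run_closed_loop."""
        sched = [(0.0, self.baseline_delay_ms)]
        for p in self.participants[participant][trial]:
            sched.append((p.onset_s, p.delay_ms))
            sched.append((p.onset_s + p.duration_s, self.baseline_delay_ms))
        return sched


def _percept_like_trial(rng: np.random.Generator, levels: Sequence[float],
                        reps: int, period_s: float, iti_lo: float,
                        iti_hi: float) -> tuple[list[DelayPeriod], float]:
    delays = list(levels) * reps
    rng.shuffle(delays)
    periods = []
    t = rng.uniform(iti_lo, iti_hi)
    for d in delays:
        periods.append(DelayPeriod(onset_s=round(t, 3), delay_ms=float(d),
                                   duration_s=period_s))
        t += period_s + rng.uniform(iti_lo, iti_hi)
    return periods, t


def make_session(experiment: str, seed: int = 0, participants: int = 1,
                 n_trials: int | None = None,
                 levels: Sequence[float] = EXP2_PERCEPT_DELAYS_MS) -> SessionDesign:
    """Instantiate a full delay-period schedule for one experiment tag."""
    if experiment not in EXPERIMENT_TAGS:
        raise ValueError(
            f"unknown experiment tag {experiment!r}; valid tags: {EXPERIMENT_TAGS}"
        )
    rng = np.random.default_rng(seed)
    parts: list[list[list[DelayPeriod]]] = []
    if experiment == "exp1":
        # one 60 s trial per delay condition
        dur = 60.0
        for _ in range(participants):
            parts.append([[DelayPeriod(0.0, float(d), dur)] for d in EXP1_DELAYS_MS])
        return SessionDesign(experiment, parts, dur)
    if experiment == "exp2-vest":
        # four 20 s trials per delay condition
        dur = 20.0
        for _ in range(participants):
            trials = [[DelayPeriod(0.0, float(d), dur)]
                      for d in EXP2_VEST_DELAYS_MS for _rep in range(4)]
            parts.append(trials)
        return SessionDesign(experiment, parts, dur)
    if experiment == "training":
        # ten 10 min trials (two per day over five days), all 400 ms
        dur = 600.0
        nt = 10 if n_trials is None else n_trials
        for _ in range(participants):
            parts.append([[DelayPeriod(0.0, 400.0, dur)] for _t in range(nt)])
        return SessionDesign(experiment, parts, dur)
    if experiment == "exp2-percept":
        nt = 10 if n_trials is None else n_trials
        dur = 260.0
        for _ in range(participants):
            trials = []
            for _t in range(nt):
                periods, end = _percept_like_trial(rng, levels, 2, 8.0, 7.0, 10.0)
                dur = max(dur, end)
                trials.append(periods)
            parts.append(trials)
        return SessionDesign(experiment, parts, math.ceil(dur))
    # exp3: 14 periods of 200 ms per trial, 6 trials, 8-9 s intervals
    nt = 6 if n_trials is None else n_trials
    dur = 260.0
    for _ in range(participants):
        trials = []
        for _t in range(nt):
            periods, end = _percept_like_trial(rng, [200.0] * 14, 1, 8.0, 8.0, 9.0)
            dur = max(dur, end)
            trials.append(periods)
        parts.append(trials)
    return SessionDesign("exp3", parts, math.ceil(dur))


def generate_button(periods: Sequence[DelayPeriod], truth: PerceptTruth,
                    duration_s: float, fs: float, seed: int = 0,
                    baseline_delay_ms: float = BASELINE_DELAY_MS) -> np.ndarray:
    """Binary button-state series for one trial's delay periods.

    Each period is detected with the mixture-model probability of its delay
    magnitude (relative to baseline); detections produce a press at onset +
    a shifted-lognormal latency truncated to the period, released shortly
    after the period ends.  Seeded false presses occur between periods.
    """
    n = int(round(duration_s * fs))
    btn = np.zeros(n, dtype=np.int8)
    rng = np.random.default_rng(seed)
    for p in periods:
        x_s = p.delay_ms / 1000.0
        if rng.random() >= float(truth.detect_probability(x_s)):
            continue
        lat = truth.latency_floor_s + rng.lognormal(truth.latency_log_mean - 1.0,
                                                    truth.latency_log_sd)
        lat = min(lat, p.duration_s - 1.0 / fs)
        i0 = int(round((p.onset_s + lat) * fs))
        i1 = int(round((p.onset_s + p.duration_s + 0.5) * fs))
        btn[i0:min(i1, n)] = 1
    # false presses in the gaps
    lam = truth.false_press_rate_per_min / 60.0 * duration_s
    for _ in range(rng.poisson(lam)):
        t0 = rng.uniform(0, duration_s - 1.0)
        i0 = int(round(t0 * fs))
        btn[i0:i0 + int(round(0.8 * fs))] = 1
    return btn


def _attenuation_schedule(periods: Sequence[DelayPeriod], decay_tau_s: float,
                          recover_tau_s: float = 1.0, floor: float = 0.1):
    """Gain schedule dropping exponentially (tau=decay_tau) inside each delay
    period toward ``floor`` and recovering exponentially afterwards."""

    def schedule(t: np.ndarray) -> np.ndarray:
        g = np.ones_like(t, dtype=float)
        for p in periods:
            inside = (t >= p.onset_s) & (t < p.onset_s + p.duration_s)
            tt = t[inside] - p.onset_s
            g[inside] = floor + (1 - floor) * np.exp(-tt / decay_tau_s)
            end = p.onset_s + p.duration_s
            after = t >= end
            g_end = floor + (1 - floor) * math.exp(-p.duration_s / decay_tau_s)
            ta = t[after] - end
            g[after] = np.minimum(g[after], 1 + (g_end - 1) * np.exp(-ta / recover_tau_s))
        return np.clip(g, 0.0, 1.0)

    return schedule


def synthesize_experiment(experiment: str, seed: int = 0, participants: int = 1,
                          plant_params=None, limits=None, ctrl=None,
                          truth: PerceptTruth | None = None,
                          evs_rms_ma: float = 1.38,
                          coupling_amplitude: float = 1.0,
                          attenuation_tau_s: float = 1.5,
                          fs: float | None = None) -> tuple[list[TrialRecord], dict]:
    """End-to-end synthetic dataset for an experiment tag.

    Returns (trials, ground_truth_sidecar).  Trials carry EVS/EMG channels for
    the vestibular experiments and button state for the perceptual ones.
    """
    from .plant import LimitConfig, PendulumParams
    from .controller import ControllerParams, run_closed_loop

    if plant_params is None:
        plant_params = PendulumParams(fs=fs or 2000.0)
    elif fs is not None and plant_params.fs != fs:
        raise ValueError("pass fs either via plant_params or the fs argument, not both")
    if limits is None:
        limits = LimitConfig()
    if ctrl is None:
        ctrl = ControllerParams()
    if truth is None:
        truth = PerceptTruth()
    design = make_session(experiment, seed=seed, participants=participants)
    rng = np.random.default_rng(seed + 1)
    needs_evs = experiment in ("exp2-vest", "exp3")
    needs_button = experiment in ("exp2-percept", "exp3")
    trials: list[TrialRecord] = []
    for pi, ptrials in enumerate(design.participants):
        for ti, periods in enumerate(ptrials):
            sched = design.trial_schedule(pi, ti)
            trial_seed = int(rng.integers(2**31))
            res = run_closed_loop(plant_params, limits, ctrl, sched,
                                  design.trial_duration_s, seed=trial_seed)
            trial = res.trial
            if needs_evs:
                evs = generate_evs(EVSConfig(duration_s=design.trial_duration_s,
                                             fs=plant_params.fs, target_rms=evs_rms_ma,
                                             seed=trial_seed + 1))
                if experiment == "exp3":
                    gain_sched = _attenuation_schedule(periods, attenuation_tau_s)
                else:
                    gain_sched = None
                coupling = VestibularCoupling(fs=plant_params.fs,
                                              amplitude=coupling_amplitude,
                                              gain_schedule=gain_sched)
                trial.evs_ma = evs
                trial.emg_au = generate_emg(trial, evs, coupling, tonic=1.0,
                                            noise_std=0.2, seed=trial_seed + 2)
            if needs_button:
                trial.button = generate_button(periods, truth,
                                               design.trial_duration_s,
                                               plant_params.fs, seed=trial_seed + 3)
            trial.meta.update({
                "experiment": experiment,
                "participant": pi,
                "trial": ti,
                "periods": [[p.onset_s, p.delay_ms, p.duration_s] for p in periods],
            })
            trials.append(trial)
    sidecar = {
        "experiment": experiment,
        "seed": seed,
        "participants": participants,
        "truth": {
            "mu_s": truth.mu_s, "sigma_s": truth.sigma_s, "delta": truth.delta,
            "coupling_amplitude": coupling_amplitude,
            "attenuation_tau_s": attenuation_tau_s,
            "evs_rms_ma": evs_rms_ma,
        },
        "controller": {"kp": ctrl.kp, "kd": ctrl.kd,
                       "intrinsic_delay_ms": ctrl.intrinsic_delay_ms,
                       "noise_std": ctrl.noise_std},
    }
    return trials, sidecar
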