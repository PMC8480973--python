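"""Detection classification and Bayesian lapse-mixture psychometric fitting.

The mixture model is p(x | mu, sigma, delta) = delta/2 + (1-delta)*Phi((x-mu)/sigma).
Fitting is a grid posterior (uniform prior) over mu, sigma, delta; delta is
marginalized out before taking the (mu, sigma) mode, and the 70% threshold is
the posterior-weighted average of the per-cell interpolated 70% point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr, ndtri

from .signals import DelayPeriod

__all__ = [
    "PeriodOutcome",
    "PsychometricGrid",
    "PsychometricPosterior",
    "classify_periods",
    "detection_table",
    "mixture_probability",
    "fit_psychometric",
    "threshold70",
]


@dataclass
class PeriodOutcome:
    period: DelayPeriod
    status: str  # detected | missed | excluded
    detection_time_s: float | None = None


def classify_periods(button: np.ndarray, fs: float,
                     periods: list[DelayPeriod]) -> list[PeriodOutcome]:
    """Label each delay period as detected/missed/excluded from the button trace.

    Excluded: the button was already pressed before the onset and held
    through it.  Detected: any press sample within the period (detection
    time = first press minus onset).  Otherwise missed.
    """
    btn = np.asarray(button).astype(bool)
    n = btn.size
    ordered = sorted(periods, key=lambda p: p.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if a.onset_s + a.duration_s > b.onset_s:
            raise ValueError("design error: overlapping delay periods")
    out = []
    for p in periods:
        i0 = int(round(p.onset_s * fs))
        i1 = min(int(round((p.onset_s + p.duration_s) * fs)), n)
        if i0 >= n:
            raise ValueError("delay period lies beyond the button trace")
        if i0 > 0 and btn[i0] and btn[i0 - 1]:
            out.append(PeriodOutcome(p, "excluded"))
            continue
        seg = btn[i0:i1]
        hits = np.flatnonzero(seg)
        if hits.size:
            out.append(PeriodOutcome(p, "detected", detection_time_s=hits[0] / fs))
        else:
            out.append(PeriodOutcome(p, "missed"))
    return out


def detection_table(outcomes: list[PeriodOutcome]) -> pd.DataFrame:
    """Per-delay presented/excluded/used/detected counts, exact and rounded
    percent detected, and mean detection time."""
    rows = {}
    for o in outcomes:
        d = float(o.period.delay_ms)
        r = rows.setdefault(d, {"presented": 0, "excluded": 0, "detected": 0,
                                "times": []})
        r["presented"] += 1
        if o.status == "excluded":
            r["excluded"] += 1
        elif o.status == "detected":
            r["detected"] += 1
            r["times"].append(o.detection_time_s)
    recs = []
    for d in sorted(rows):
        r = rows[d]
        used = r["presented"] - r["excluded"]
        frac = r["detected"] / used if used else float("nan")
        recs.append({
            "delay_ms": d,
            "presented": r["presented"],
            "excluded": r["excluded"],
            "used": used,
            "detected": r["detected"],
            "fraction_detected": frac,
            "percent_detected": int(round(100 * frac)) if used else None,
            "mean_detection_time_s": float(np.mean(r["times"])) if r["times"] else float("nan"),
        })
    return pd.DataFrame.from_records(recs)


def mixture_probability(x, mu, sigma, delta):
    """delta/2 + (1-delta)*Phi((x-mu)/sigma); x, mu, sigma in seconds."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    delta = np.asarray(delta, dtype=float)
    if np.any((delta < 0) | (delta > 1)):
        raise ValueError("delta must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    return delta / 2.0 + (1.0 - delta) * ndtr((x - mu) / sigma)


@dataclass(frozen=True)
class PsychometricGrid:
    """Default grids: mu 0..0.5 step 0.005 (s), sigma 0.01..5 step 0.01,
    delta 0.01..0.05 step 0.01."""

    mu: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.0, 0.5 + 1e-9, 0.005), 6))
    sigma: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.01, 5.0 + 1e-9, 0.01), 6))
    delta: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.01, 0.05 + 1e-9, 0.01), 6))


@dataclass
class PsychometricPosterior:
    grid: PsychometricGrid
    joint: np.ndarray              # (n_mu, n_sigma) posterior after delta marginalization
    delta_mean: np.ndarray         # posterior-mean delta per (mu, sigma) cell
    mode: tuple[float, float]      # (mu*, sigma*)
    mode_at_edge: bool
    threshold70_s: float

    def sum(self) -> float:
        return float(self.joint.sum())


def fit_psychometric(delays_s, detected, used,
                     grid: PsychometricGrid | None = None,
                     threshold_p: float = 0.70,
                     fixed_delta: float | None = None) -> PsychometricPosterior:
    """Grid posterior over (mu, sigma, delta) from per-level binomial counts.

    ``fixed_delta`` switches the threshold interpolation from the
    posterior-mean delta per cell to a fixed value.
    """
    x = np.asarray(delays_s, dtype=float)
    k = np.asarray(detected, dtype=float)
    n = np.asarray(used, dtype=float)
    if x.size == 0:
        raise ValueError("empty counts")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct delay levels")
    if grid is None:
        grid = PsychometricGrid()
    mu = grid.mu[:, None, None]          # (M, 1, 1)
    sigma = grid.sigma[None, :, None]    # (1, S, 1)
    loglik = np.zeros((grid.mu.size, grid.sigma.size, grid.delta.size))
    eps = 1e-12
    for di, d in enumerate(grid.delta):
        # (M, S, levels)
        p = d / 2.0 + (1.0 - d) * ndtr((x[None, None, :] - mu) / sigma)
        p = np.clip(p, eps, 1 - eps)
        loglik[:, :, di] = (k[None, None, :] * np.log(p)
                            + (n - k)[None, None, :] * np.log1p(-p)).sum(axis=-1)
    logpost = loglik - logsumexp(loglik)
    post3 = np.exp(logpost)
    joint = post3.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_mean = (post3 * grid.delta[None, None, :]).sum(axis=2) / np.maximum(joint, 1e-300)
    im, isig = np.unravel_index(np.argmax(joint), joint.shape)
    edge = im in (0, grid.mu.size - 1) or isig in (0, grid.sigma.size - 1)
    dbar = np.full_like(joint, fixed_delta) if fixed_delta is not None else delta_mean
    # per-cell delay where the delta-averaged curve crosses threshold_p
    arg = (threshold_p - dbar / 2.0) / (1.0 - dbar)
    arg = np.clip(arg, eps, 1 - eps)
    xcell = grid.mu[:, None] + grid.sigma[None, :] * ndtri(arg)
    thr = float((joint * xcell).sum())
    return PsychometricPosterior(grid=grid, joint=joint, delta_mean=delta_mean,
                                 mode=(float(grid.mu[im]), float(grid.sigma[isig])),
                                 mode_at_edge=edge, threshold70_s=thr)


def threshold70(posterior: PsychometricPosterior) -> float:
    return posterior.threshold70_s
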