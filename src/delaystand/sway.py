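"""Sway-behavior measures: 2 s windowed velocity variance, percent time within
limits, sliding-window variance, pre-detection peaks, and exponential fits."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "WindowSet",
    "ExpFit",
    "extract_windows",
    "sway_velocity_variance",
    "percent_within_limits",
    "sliding_velocity_variance",
    "peak_variance_before_detection",
    "fit_exponential",
    "central_velocity",
]


@dataclass
class WindowSet:
    """Disjoint 2 s analysis windows, each inside a continuous in-limit run."""

    windows: list[tuple[float, float]]  # (start_s, end_s)
    window_s: float
    fs: float

    def __len__(self) -> int:
        return len(self.windows)


def in_limit_mask(theta_deg: np.ndarray, anterior_limit: float = 6.0,
                  posterior_limit: float = -3.0) -> np.ndarray:
    theta_deg = np.asarray(theta_deg, dtype=float)
    return (theta_deg >= posterior_limit) & (theta_deg <= anterior_limit)


def extract_windows(theta_deg: np.ndarray, fs: float, anterior_limit: float = 6.0,
                    posterior_limit: float = -3.0, window_s: float = 2.0,
                    t0: float = 0.0) -> WindowSet:
    """Pack floor(run/2s) non-overlapping windows from the start of each
    maximal continuous in-limit run."""
    mask = in_limit_mask(theta_deg, anterior_limit, posterior_limit)
    wlen = int(round(window_s * fs))
    windows: list[tuple[float, float]] = []
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        run = j - i
        for k in range(run // wlen):
            s = i + k * wlen
            windows.append((t0 + s / fs, t0 + (s + wlen) / fs))
        i = j
    return WindowSet(windows=windows, window_s=window_s, fs=fs)


def central_velocity(theta_deg: np.ndarray, fs: float) -> np.ndarray:
    """Angular velocity (deg/s) by central finite differences, one-sided at edges."""
    return np.gradient(np.asarray(theta_deg, dtype=float), 1.0 / fs)


def sway_velocity_variance(theta_dot_dps: np.ndarray, fs: float,
                           windows: WindowSet, t0: float = 0.0) -> tuple[float, int]:
    """Mean of per-window sample variances of sway velocity; (nan, 0) if no windows."""
    if len(windows) == 0:
        return float("nan"), 0
    v = np.asarray(theta_dot_dps, dtype=float)
    out = []
    for (a, b) in windows.windows:
        i0 = int(round((a - t0) * fs))
        i1 = int(round((b - t0) * fs))
        out.append(np.var(v[i0:i1], ddof=1))
    return float(np.mean(out)), len(out)


def percent_within_limits(theta_deg: np.ndarray, fs: float,
                          anterior_limit: float = 6.0, posterior_limit: float = -3.0,
                          interval_s: float = 60.0,
                          allow_short: bool = False) -> np.ndarray:
    """Percent of samples within the limits, per consecutive interval."""
    mask = in_limit_mask(theta_deg, anterior_limit, posterior_limit)
    ilen = int(round(interval_s * fs))
    if len(mask) < ilen and not allow_short:
        raise ValueError(
            f"trace shorter than one {interval_s} s interval; pass allow_short=True"
        )
    if len(mask) < ilen:
        return np.array([100.0 * mask.mean()])
    k = len(mask) // ilen
    out = mask[:k * ilen].reshape(k, ilen).mean(axis=1) * 100.0
    return out


def sliding_velocity_variance(theta_dot_dps: np.ndarray, fs: float,
                              window_s: float = 2.0) -> np.ndarray:
    """Centered moving sample variance (ddof=1), one value per sample.

    Edge windows shrink to the available samples; windows with fewer than two
    samples yield 0.
    """
    v = np.asarray(theta_dot_dps, dtype=float)
    n = v.size
    wlen = int(round(window_s * fs))
    if n <= 1:
        return np.zeros(n)
    half_lo = (wlen - 1) // 2
    half_hi = wlen - 1 - half_lo
    # prefix sums for O(n) exact windowed moments
    c1 = np.concatenate(([0.0], np.cumsum(v)))
    c2 = np.concatenate(([0.0], np.cumsum(v * v)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    m = (hi - lo).astype(float)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1 * s1 / m) / (m - 1)
    var[m < 2] = 0.0
    return np.maximum(var, 0.0)


def peak_variance_before_detection(variance: np.ndarray, fs: float,
                                   onset_s: float, press_s: float,
                                   t0: float = 0.0) -> float:
    """Maximum sliding variance on [onset, press]; press <= onset marks an
    excluded transition."""
    if press_s <= onset_s:
        raise ValueError("excluded transition: press precedes delay onset")
    i0 = int(round((onset_s - t0) * fs))
    i1 = int(round((press_s - t0) * fs)) + 1
    seg = np.asarray(variance, dtype=float)[max(i0, 0):i1]
    if seg.size == 0:
        raise ValueError("empty interval between onset and press")
    return float(seg.max())


@dataclass
class ExpFit:
    """Least-squares fit of f(x) = a*exp(-x/b) + c."""

    a: float
    b: float
    c: float
    residual_norm: float
    identifiable: bool = True

    @property
    def value_at_tc(self) -> float:
        """f(b): value at one time constant (63.2% of the change completed)."""
        return self.a * math.exp(-1.0) + self.c

    @property
    def attenuation95_x(self) -> float:
        """x at 95% attenuation, i.e. three time constants."""
        return 3.0 * self.b

    def __call__(self, x):
        return self.a * np.exp(-np.asarray(x, dtype=float) / self.b) + self.c


def _profile_fit(x: np.ndarray, y: np.ndarray, b: float) -> tuple[float, float, float]:
    """Exact linear least squares for (a, c) at fixed b; returns (a, c, rss)."""
    e = np.exp(-x / b)
    design = np.column_stack([e, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ coef
    return float(coef[0]), float(coef[1]), float(r @ r)


def fit_exponential(x: np.ndarray, y: np.ndarray) -> ExpFit:
    """Nonlinear least squares for a*exp(-x/b)+c with multi-start b initialization.

    The time constant is profiled over a logarithmic grid spanning
    [range/100, range*10], then polished with a full nonlinear fit.
    Degenerate (flat) data return a ≈ 0 with ``identifiable=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter exponential")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    span = x[-1] - x[0]
    bgrid = np.geomspace(span / 100.0, span * 10.0, 25)
    best = None
    for b in bgrid:
        a, c, rss = _profile_fit(x, y, b)
        if best is None or rss < best[3]:
            best = (a, b, c, rss)
    a0, b0, c0, rss0 = best

    def model(xx, a, b, c):
        return a * np.exp(-xx / b) + c

    try:
        popt, _ = curve_fit(model, x, y, p0=[a0, b0, c0],
                            bounds=([-np.inf, span / 1e4, -np.inf],
                                    [np.inf, span * 1e3, np.inf]),
                            maxfev=20000)
        a, b, c = (float(v) for v in popt)
        r = y - model(x, a, b, c)
        rss = float(r @ r)
        if rss > rss0:  # polish made it worse; keep the profile solution
            a, b, c, rss = a0, b0, c0, rss0
    except RuntimeError:
        a, b, c, rss = a0, b0, c0, rss0

    yscale = max(float(np.ptp(y)), abs(float(np.mean(y))), 1e-30)
    identifiable = abs(a) > 1e-6 * yscale
    return ExpFit(a=a, b=b, c=c, residual_norm=math.sqrt(rss),
                  identifiable=identifiable)
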