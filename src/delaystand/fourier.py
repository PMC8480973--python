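"""Segment-averaged Fourier analysis of stimulus-EMG coupling.

Disjoint segments of ``nfft`` samples are transformed, auto/cross spectra
averaged over segments, and coherence, gain and cross-covariance derived from
the averaged spectra.  The coherence 95% confidence limit is
``1 - 0.05**(1/(L-1))`` for L disjoint segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectraSet",
    "CouplingEstimates",
    "preprocess_emg",
    "scale_emg",
    "segment_spectra",
    "coherence",
    "coherence_limit",
    "gain",
    "cross_covariance",
    "peak_to_peak",
    "pool_participants",
    "coupling_estimates",
    "bootstrap_covariance_interval",
]

SHORT_WINDOW_S = (0.050, 0.070)
MEDIUM_WINDOW_S = (0.100, 0.120)


def preprocess_emg(raw: np.ndarray, fs: float, cutoff_hz: float = 30.0,
                   design_order: int = 3, order6_twice: bool = False) -> np.ndarray:
    """High-pass (30 Hz, zero-lag, overall order 6) then full-wave rectify.

    Zero lag comes from forward-backward filtering; by default an order-3
    Butterworth is applied twice (overall order 6).  Set ``order6_twice`` to
    apply an order-6 design twice instead.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"fs={fs} too low for a {cutoff_hz} Hz high-pass")
    order = 6 if order6_twice else design_order
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return np.abs(sps.sosfiltfilt(sos, np.asarray(raw, dtype=float)))


def scale_emg(envelope: np.ndarray, quiet_envelope: np.ndarray,
              quiet_theta_deg: np.ndarray, posture_band_deg: float = 0.25) -> np.ndarray:
    """Scale an envelope by the mean quiet-standing envelope near preferred posture.

    The baseline mean uses only quiet-trial samples within +-band of the
    quiet trial's median angle; output is in fractions of baseline EMG.
    """
    theta = np.asarray(quiet_theta_deg, dtype=float)
    q = np.asarray(quiet_envelope, dtype=float)
    mask = np.abs(theta - np.median(theta)) <= posture_band_deg
    if not mask.any():
        raise ValueError(
            f"no quiet-standing samples within +-{posture_band_deg} deg of the "
            "preferred posture; cannot compute baseline EMG"
        )
    base = q[mask].mean()
    if base <= 0:
        raise ValueError("baseline EMG mean is not positive")
    return np.asarray(envelope, dtype=float) / base


@dataclass
class SpectraSet:
    """Segment-averaged auto/cross spectra (full two-sided arrays of length nfft)."""

    fs: float
    nfft: int
    L: int
    pss: np.ndarray = field(repr=False)  # stimulus autospectrum, real
    prr: np.ndarray = field(repr=False)  # response autospectrum, real
    psr: np.ndarray = field(repr=False)  # cross spectrum conj(S)*R, complex

    @property
    def df(self) -> float:
        """Frequency resolution fs/nfft."""
        return self.fs / self.nfft

    @property
    def frequencies(self) -> np.ndarray:
        """One-sided frequency axis (0 .. fs/2)."""
        return np.arange(self.nfft // 2 + 1) * self.df

    def onesided(self, arr: np.ndarray) -> np.ndarray:
        return arr[: self.nfft // 2 + 1]


def segment_spectra(evs: np.ndarray, emg: np.ndarray, nfft: int = 2048,
                    fs: float = 2000.0, demean: bool = True) -> SpectraSet:
    """Average periodograms of disjoint non-overlapping segments (rectangular window)."""
    x = np.asarray(evs, dtype=float)
    y = np.asarray(emg, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"evs and emg lengths differ: {x.size} vs {y.size}")
    L = x.size // nfft
    if L == 0:
        raise ValueError(f"need at least one full segment of {nfft} samples, got {x.size}")
    xs = x[: L * nfft].reshape(L, nfft)
    ys = y[: L * nfft].reshape(L, nfft)
    if demean:
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
    fx = np.fft.fft(xs, axis=1)
    fy = np.fft.fft(ys, axis=1)
    norm = 1.0 / (L * nfft)
    pss = (np.abs(fx) ** 2).sum(axis=0) * norm
    prr = (np.abs(fy) ** 2).sum(axis=0) * norm
    psr = (np.conj(fx) * fy).sum(axis=0) * norm
    return SpectraSet(fs=fs, nfft=nfft, L=L, pss=pss, prr=prr, psr=psr)


def coherence_limit(L: int, alpha: float = 0.05) -> float:
    """Confidence limit for coherence from L disjoint segments: 1 - alpha**(1/(L-1))."""
    if L < 2:
        raise ValueError("coherence limit requires L >= 2 segments")
    return 1.0 - alpha ** (1.0 / (L - 1))


def coherence(spectra: SpectraSet, alpha: float = 0.05):
    """One-sided coherence |Psr|^2/(Pss*Prr) with its confidence limit.

    Returns (frequencies, C, limit); frequencies where an autospectrum is
    zero yield NaN (flagged as undefined).
    """
    pss = spectra.onesided(spectra.pss)
    prr = spectra.onesided(spectra.prr)
    psr = spectra.onesided(spectra.psr)
    denom = pss * prr
    c = np.full(denom.shape, np.nan)
    ok = denom > 0
    c[ok] = (np.abs(psr[ok]) ** 2) / denom[ok]
    return spectra.frequencies, c, coherence_limit(spectra.L, alpha)


def gain(spectra: SpectraSet, alpha: float = 0.05):
    """|Psr|/Pss per frequency with a reliability mask (True where coherence
    exceeds its confidence limit)."""
    freqs, c, limit = coherence(spectra, alpha)
    pss = spectra.onesided(spectra.pss)
    g = np.full(pss.shape, np.nan)
    ok = pss > 0
    g[ok] = np.abs(spectra.onesided(spectra.psr)[ok]) / pss[ok]
    reliable = np.nan_to_num(c, nan=0.0) > limit
    return freqs, g, reliable


def cross_covariance(spectra: SpectraSet):
    """Inverse transform of the averaged cross spectrum with a 95% interval.

    Positive lag means the EMG lags the stimulus.  The interval is the
    independence approximation 1.96*sqrt(sum(Pss*Prr)/(L*nfft^2)).
    """
    q = np.fft.ifft(spectra.psr)
    q = np.real(np.fft.fftshift(q))
    n = spectra.nfft
    lags = (np.arange(n) - n // 2) / spectra.fs
    var = float(np.sum(spectra.pss * spectra.prr)) / (spectra.L * n * n)
    ci95 = 1.96 * math.sqrt(var)
    return lags, q, ci95


def bootstrap_covariance_interval(spectra: SpectraSet, n_boot: int = 200,
                                  seed: int = 0) -> float:
    """Phase-randomization cross-check of the cross-covariance 95% interval.

    Randomizes the cross-spectrum phase (destroying any coupling while
    keeping the auto spectra) and returns the 95th percentile of |q| pooled
    over lags and replicates.
    """
    rng = np.random.default_rng(seed)
    n = spectra.nfft
    amp = np.sqrt(spectra.pss * spectra.prr / spectra.L)
    vals = np.empty(n_boot)
    half = n // 2
    for b in range(n_boot):
        z = np.empty(n, dtype=complex)
        phase = rng.uniform(0, 2 * np.pi, half - 1)
        z[1:half] = amp[1:half] * np.exp(1j * phase)
        z[half + 1:] = np.conj(z[1:half][::-1])  # Hermitian symmetry: q is real
        z[0] = amp[0] * rng.choice([-1.0, 1.0])
        z[half] = amp[half] * rng.choice([-1.0, 1.0])
        q = np.real(np.fft.ifft(z))
        vals[b] = np.percentile(np.abs(q), 95)
    return float(np.mean(vals))


def _extremum_in_window(lags, q, window_s):
    mask = (lags >= window_s[0]) & (lags <= window_s[1])
    seg = q[mask]
    if seg.size == 0:
        return 0.0, float("nan")
    i = int(np.argmax(np.abs(seg)))
    return float(seg[i]), float(lags[mask][i])


def peak_to_peak(lags: np.ndarray, q: np.ndarray, ci95: float,
                 short_window_s=SHORT_WINDOW_S, medium_window_s=MEDIUM_WINDOW_S):
    """Biphasic response amplitude from the short/medium latency windows.

    The extremum in each window is zeroed when it does not exceed the 95%
    interval; the amplitude is |short - medium| of the (possibly zeroed)
    values.  Returns a dict with values, latencies and the amplitude.
    """
    s_val, s_lat = _extremum_in_window(lags, q, short_window_s)
    m_val, m_lat = _extremum_in_window(lags, q, medium_window_s)
    s_sig = abs(s_val) > ci95
    m_sig = abs(m_val) > ci95
    s_used = s_val if s_sig else 0.0
    m_used = m_val if m_sig else 0.0
    return {
        "short_value": s_used, "short_latency_s": s_lat, "short_significant": s_sig,
        "medium_value": m_used, "medium_latency_s": m_lat, "medium_significant": m_sig,
        "amplitude": abs(s_used - m_used),
    }


def pool_participants(spectra_list: list[SpectraSet]) -> SpectraSet:
    """Segment-weighted pooling across participants (as if data were concatenated)."""
    if not spectra_list:
        raise ValueError("nothing to pool")
    s0 = spectra_list[0]
    for s in spectra_list[1:]:
        if s.nfft != s0.nfft or s.fs != s0.fs:
            raise ValueError("mismatched nfft/fs across participants")
    total = sum(s.L for s in spectra_list)
    pss = sum(s.pss * s.L for s in spectra_list) / total
    prr = sum(s.prr * s.L for s in spectra_list) / total
    psr = sum(s.psr * s.L for s in spectra_list) / total
    return SpectraSet(fs=s0.fs, nfft=s0.nfft, L=total, pss=pss, prr=prr, psr=psr)


@dataclass
class CouplingEstimates:
    """Bundle of coherence/gain/cross-covariance summaries from one SpectraSet."""

    frequencies: np.ndarray
    coherence: np.ndarray
    coherence_limit: float
    gain: np.ndarray
    gain_reliable: np.ndarray
    lags_s: np.ndarray
    cross_covariance: np.ndarray
    cc_interval95: float
    peaks: dict
    L: int


def coupling_estimates(spectra: SpectraSet, alpha: float = 0.05) -> CouplingEstimates:
    freqs, c, limit = coherence(spectra, alpha)
    _, g, reliable = gain(spectra, alpha)
    lags, q, ci = cross_covariance(spectra)
    peaks = peak_to_peak(lags, q, ci)
    return CouplingEstimates(frequencies=freqs, coherence=c, coherence_limit=limit,
                             gain=g, gain_reliable=reliable, lags_s=lags,
                             cross_covariance=q, cc_interval95=ci, peaks=peaks,
                             L=spectra.L)
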