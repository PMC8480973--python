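"""Morlet-wavelet time-frequency stimulus-EMG coupling around delay transitions.

The bank holds 40 complex Morlet wavelets with peak frequencies linearly
spaced 0.5-25 Hz and cycle counts geometrically spaced 3-12.  Per-transition
wavelet cross/auto products are averaged across transitions to form
time-resolved coherence and gain maps; the first and last 2 s of each
segment are trimmed against edge distortion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .sway import ExpFit, fit_exponential

__all__ = [
    "Wavelet",
    "WaveletBank",
    "TimeFrequencyMap",
    "build_bank",
    "morlet_kernel",
    "tf_coupling",
    "band_mean",
    "fit_attenuation",
    "attenuation_at",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class Wavelet:
    freq_hz: float
    cycles: float

    @property
    def sigma_t(self) -> float:
        """Gaussian-envelope std (s): n cycles spread over 2*pi*f."""
        return self.cycles / (2.0 * math.pi * self.freq_hz)

    @property
    def fwhm_t(self) -> float:
        """Temporal FWHM (s) = 2*sqrt(2 ln 2) * n / (2 pi f)."""
        return _FWHM * self.sigma_t

    @property
    def fwhm_f(self) -> float:
        """Spectral FWHM (Hz) = 2*sqrt(2 ln 2) * f / n."""
        return _FWHM * self.freq_hz / self.cycles


@dataclass
class WaveletBank:
    wavelets: list[Wavelet]

    def __len__(self) -> int:
        return len(self.wavelets)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([w.freq_hz for w in self.wavelets])

    @property
    def fwhm_t(self) -> np.ndarray:
        return np.array([w.fwhm_t for w in self.wavelets])

    @property
    def fwhm_f(self) -> np.ndarray:
        return np.array([w.fwhm_f for w in self.wavelets])


def build_bank(f_lo: float = 0.5, f_hi: float = 25.0, n_freqs: int = 40,
               cycles_lo: float = 3.0, cycles_hi: float = 12.0) -> WaveletBank:
    """Bank with linear frequency spacing and geometric cycle spacing."""
    freqs = np.linspace(f_lo, f_hi, n_freqs)
    cycles = np.geomspace(cycles_lo, cycles_hi, n_freqs)
    return WaveletBank([Wavelet(float(f), float(c)) for f, c in zip(freqs, cycles)])


def morlet_kernel(w: Wavelet, fs: float, n_sigmas: float = 4.0) -> np.ndarray:
    """Sampled zero-mean complex Morlet wavelet (Gaussian-tapered sinusoid)."""
    half = int(math.ceil(n_sigmas * w.sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    g = np.exp(-0.5 * (t / w.sigma_t) ** 2)
    k = g * np.exp(2j * math.pi * w.freq_hz * t)
    k = k - k.mean()  # enforce exact zero mean
    return k


@dataclass
class TimeFrequencyMap:
    """Coherence/gain on a (frequency x time) grid around a delay transition."""

    times_s: np.ndarray            # relative to transition onset at 0
    frequencies: np.ndarray
    coherence: np.ndarray          # (n_freq, n_time)
    gain: np.ndarray
    mask: np.ndarray               # True where coherence exceeds its limit
    coherence_limit: float
    n_transitions: int
    trim_s: float


def _convolve_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-mode complex convolution with reflection padding at the edges."""
    half = len(kernel) // 2
    pad = min(half, len(x) - 1)
    xp = np.pad(x, pad, mode="reflect")
    out = sps.fftconvolve(xp, kernel, mode="same")
    return out[pad:pad + len(x)]


def tf_coupling(segments, fs: float, bank: WaveletBank | None = None,
                pre_s: float = 8.0, trim_s: float = 2.0,
                alpha: float = 0.01) -> TimeFrequencyMap:
    """Transition-averaged wavelet coherence and gain.

    ``segments`` is a list of (evs, emg) arrays of equal length, each aligned
    so the delay transition occurs ``pre_s`` seconds in.  Cross/auto wavelet
    products are averaged across transitions (K), with significance limit
    ``1 - alpha**(1/(K-1))``.
    """
    if bank is None:
        bank = build_bank()
    K = len(segments)
    if K < 2:
        raise ValueError("coherence needs at least 2 transitions")
    n = len(segments[0][0])
    for x, y in segments:
        if len(x) != n or len(y) != n:
            raise ValueError("all transition segments must have equal length")
    nf = len(bank)
    sxx = np.zeros((nf, n))
    syy = np.zeros((nf, n))
    sxy = np.zeros((nf, n), dtype=complex)
    for fi, w in enumerate(bank.wavelets):
        kern = morlet_kernel(w, fs)
        for x, y in segments:
            wx = _convolve_reflect(np.asarray(x, float), kern)
            wy = _convolve_reflect(np.asarray(y, float), kern)
            sxx[fi] += np.abs(wx) ** 2
            syy[fi] += np.abs(wy) ** 2
            sxy[fi] += np.conj(wx) * wy
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) ** 2 / denom, np.nan)
        g = np.where(sxx > 0, np.abs(sxy) / sxx, np.nan)
    limit = 1.0 - alpha ** (1.0 / (K - 1))
    i0 = int(round(trim_s * fs))
    i1 = n - i0
    times = np.arange(n) / fs - pre_s
    mask = np.nan_to_num(coh, nan=0.0) > limit
    return TimeFrequencyMap(times_s=times[i0:i1], frequencies=bank.frequencies,
                            coherence=coh[:, i0:i1], gain=g[:, i0:i1],
                            mask=mask[:, i0:i1], coherence_limit=limit,
                            n_transitions=K, trim_s=trim_s)


def band_mean(tfmap: TimeFrequencyMap, f_lo: float = 0.5, f_hi: float = 25.0):
    """Band-mean coherence and (significance-masked) gain time series.

    Gain is averaged only over cells with significant coherence; time points
    with no significant cell yield NaN, reported via the gap mask.
    """
    sel = (tfmap.frequencies >= f_lo) & (tfmap.frequencies <= f_hi)
    coh = tfmap.coherence[sel]
    g = tfmap.gain[sel]
    m = tfmap.mask[sel]
    mean_coh = np.nanmean(coh, axis=0)
    counts = m.sum(axis=0)
    gsum = np.where(m, np.nan_to_num(g, nan=0.0), 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_gain = np.where(counts > 0, gsum / counts, np.nan)
    gap = counts == 0
    return mean_coh, mean_gain, gap


def fit_attenuation(times_s: np.ndarray, series: np.ndarray,
                    period=(0.0, 8.0)) -> ExpFit:
    """Exponential decay fit over the delay period; b is the 63.2% attenuation
    time and 3b the 95% attenuation time."""
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(series, dtype=float)
    sel = (t >= period[0]) & (t <= period[1]) & np.isfinite(y)
    if sel.sum() < 4:
        raise ValueError("delay period not covered by the series")
    return fit_exponential(t[sel] - period[0], y[sel])


def attenuation_at(fit: ExpFit, t_s: float) -> float:
    """Percent reduction of the decaying component at time t: 100*(1-exp(-t/b))."""
    if not fit.identifiable:
        raise ValueError("attenuation undefined for an unidentifiable fit")
    return 100.0 * (1.0 - math.exp(-t_s / fit.b))
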