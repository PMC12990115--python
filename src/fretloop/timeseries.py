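"""Time- and frequency-domain indicators for conformational dynamics.

For a distance time series x(t) this module computes:

* the normalized autocorrelation function (FFT estimator) and the
  integrated correlation time tau_corr = integral of C(tau) up to the
  first zero crossing tau_0;
* the Hurst exponent H from classical rescaled-range (R/S) analysis,
  R(n)/S(n) ~ c n^H — H = 0.5 is memoryless diffusion, H > 0.5 persistent
  motion on a rugged landscape, H < 0.5 antipersistent dynamics dominated
  by restoring forces;
* the Welch power spectral density and its high-frequency power-law
  exponent alpha (S(f) ~ f^-alpha), classified as white (alpha ~ 0),
  1/f (alpha ~ 1) or Brownian (alpha ~ 2) noise;
* the zero-lag Pearson cross-correlation between two observables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .trajectory import DistanceTrace

__all__ = [
    "ACFResult",
    "HurstResult",
    "PSDResult",
    "autocorrelation",
    "integrated_correlation_time",
    "hurst_rs",
    "welch_psd",
    "zero_lag_crosscorr",
    "classify_noise",
]


@dataclass
class ACFResult:
    """Normalized ACF with first-zero-crossing and integrated times (ps)."""

    lags: np.ndarray
    C: np.ndarray
    tau0: float
    tau_corr: float
    crossed_zero: bool


@dataclass
class HurstResult:
    H: float
    window_sizes: np.ndarray
    rs_values: np.ndarray
    fit_r2: float


@dataclass
class PSDResult:
    freqs: np.ndarray
    power: np.ndarray
    alpha: float
    noise_class: str
    fit_range: tuple[float, float]


def _acf_fft(x: np.ndarray) -> np.ndarray:
    """Biased (divide-by-N) autocorrelation via zero-padded FFT."""
    n = x.size
    x = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    if acov[0] <= 0:
        raise ValueError("zero-variance trace: ACF undefined")
    return acov / acov[0]


def autocorrelation(trace: DistanceTrace) -> ACFResult:
    """Normalized autocorrelation of a trace with its correlation times.

    The biased FFT estimator (divide by N, zero-padded against circular
    wrap-around) keeps the ACF positive semidefinite. tau_0 is the first
    zero crossing (linearly interpolated); tau_corr the trapezoidal
    integral of C up to tau_0. When C never crosses zero within the
    available lags the integral runs to the maximum lag and the result is
    flagged via ``crossed_zero=False``.
    """
    if len(trace) < 16:
        raise ValueError("trace too short for ACF (need >= 16 samples)")
    if np.ptp(trace.values) == 0:
        raise ValueError("zero-variance trace: ACF undefined")
    C = _acf_fft(trace.values)
    lags = np.arange(C.size) * trace.dt
    neg = np.nonzero(C <= 0)[0]
    if neg.size:
        k = int(neg[0])
        # Linear interpolation of the crossing between lags k-1 and k.
        c0, c1 = C[k - 1], C[k]
        frac = c0 / (c0 - c1) if c0 != c1 else 0.0
        tau0 = lags[k - 1] + frac * trace.dt
        area = np.trapezoid(C[:k], lags[:k])
        area += 0.5 * c0 * (tau0 - lags[k - 1])  # triangle to the crossing
        crossed = True
    else:
        tau0 = float(lags[-1])
        area = float(np.trapezoid(C, lags))
        crossed = False
    return ACFResult(lags, C, float(tau0), float(area), crossed)


def integrated_correlation_time(acf: ACFResult) -> float:
    """Integrated correlation time (ps), the integral of C to tau_0."""
    return acf.tau_corr


def hurst_rs(series: np.ndarray, min_window: int = 16,
             n_sizes: int = 12) -> HurstResult:
    """Hurst exponent from classical rescaled-range analysis.

    For logarithmically spaced window sizes n between ``min_window`` and
    N/4 the series is tiled with disjoint windows; within each window the
    range R of cumulative mean-subtracted deviations is divided by the
    window standard deviation S, and H is the slope of log(mean R/S)
    versus log(n).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 512:
        raise ValueError("series too short for R/S analysis (need >= 512)")
    if np.ptp(x) == 0:
        raise ValueError("constant series: S = 0")
    sizes = np.unique(np.geomspace(min_window, x.size // 4,
                                   num=max(n_sizes, 8)).astype(int))
    if sizes.size < 5:
        raise ValueError("not enough distinct window sizes")
    rs_means = np.empty(sizes.size)
    for i, n in enumerate(sizes):
        nw = x.size // n
        windows = x[: nw * n].reshape(nw, n)
        dev = windows - windows.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        R = z.max(axis=1) - z.min(axis=1)
        S = windows.std(axis=1, ddof=1)
        ok = S > 0
        rs_means[i] = np.mean(R[ok] / S[ok])
    logn = np.log(sizes)
    logrs = np.log(rs_means)
    slope, intercept, r_value, _, _ = stats.linregress(logn, logrs)
    return HurstResult(float(slope), sizes, rs_means, float(r_value ** 2))


def classify_noise(alpha: float) -> str:
    """Map a spectral exponent onto a noise regime.

    alpha ~ 0 is white noise (fast uncorrelated motions), alpha ~ 1 is
    1/f noise (scale-free coupling of time scales), alpha ~ 2 is Brownian
    noise (slow diffusive rearrangements). Boundaries at 0.5 and 1.5.
    """
    if alpha < 0.5:
        return "white"
    if alpha < 1.5:
        return "one_over_f"
    return "brownian"


def welch_psd(series: np.ndarray, segment_length: int = 1024,
              fit_fraction: float = 0.5, dt: float = 1.0,
              max_freq_fraction: float = 0.25) -> PSDResult:
    """Welch PSD with a high-frequency power-law fit S(f) ~ f^-alpha.

    Hann windows with 50% overlap. The exponent is the negative slope of
    log S versus log f over the upper ``fit_fraction`` of the
    log-frequency span. The DC bin is excluded, and so are frequencies
    above ``max_freq_fraction`` of Nyquist: for sampled diffusive signals
    the discrete-time spectrum 1/(4 sin^2(pi f dt)) bends away from the
    continuous f^-2 law near Nyquist, which would bias the exponent low.
    ``dt`` (ps) sets the frequency units (1/ps).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4 * segment_length:
        raise ValueError("series shorter than 4 segments")
    freqs, power = signal.welch(x, fs=1.0 / dt, window="hann",
                                nperseg=segment_length,
                                noverlap=segment_length // 2,
                                detrend="constant")
    keep = (freqs > 0) & (freqs <= max_freq_fraction * freqs[-1])
    f = freqs[keep]
    p = power[keep]
    logf = np.log10(f)
    f_lo = logf[-1] - fit_fraction * (logf[-1] - logf[0])
    sel = logf >= f_lo
    if sel.sum() < 4:
        raise ValueError("fit band too narrow")
    slope, *_ = stats.linregress(logf[sel], np.log10(p[sel]))
    alpha = float(-slope)
    return PSDResult(freqs, power, alpha, classify_noise(alpha),
                     (float(10 ** f_lo), float(f[-1])))


def zero_lag_crosscorr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length series at lag 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D series of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
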