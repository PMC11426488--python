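"""Head-motion analysis from a head-mounted 3-axis accelerometer.

The X axis is aligned with gravity, so up-down (pitch) head motion dominates
the X channel.  Acceleration is calibrated to units of g, low-passed at
20 Hz, and differentiated to jerk, which whitens the spectrum and removes the
gravity DC component.  Time-frequency structure of the pitch jerk is read out
with an analytic Morlet continuous wavelet transform; head-pitch activity is
summarized as the mean wavelet power in the 5-14 Hz "active search" band and
the band frequency with the highest power (dominant frequency).

Head raised/lowered state is classified from the difference of 1-s moving
medians of the Z and X channels: the pooled distribution of that difference
is fit with a three-component Gaussian mixture, and the raised threshold is
set at (mean - SD) of the component with the largest mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from sklearn.mixture import GaussianMixture

from .config import AnalysisConfig
from .plume import lowpass
from .timeseries import TimeSeries

__all__ = [
    "AccelCalibration",
    "BandPowerSeries",
    "HeadStateSeries",
    "GmmFit",
    "calibrate",
    "jerk",
    "morlet_cwt",
    "cwt_band_power",
    "head_height_signal",
    "fit_head_state_threshold",
    "classify_head_state",
]


@dataclass
class AccelCalibration:
    """Per-axis zero offset (V) and scale (V per g)."""

    zero_offset: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.zero_offset = np.atleast_1d(np.asarray(self.zero_offset, dtype=float))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=float))
        if np.any(self.scale == 0):
            raise ValueError("calibration scale must be nonzero on all axes")

    @classmethod
    def identity(cls, n_axes: int = 3) -> "AccelCalibration":
        return cls(np.zeros(n_axes), np.ones(n_axes))


def calibrate(raw: TimeSeries, cal: AccelCalibration) -> TimeSeries:
    """Convert accelerometer volts to g: ``(V - zero_offset) / scale``."""
    if raw.n_channels != 3:
        raise ValueError("expected a 3-channel accelerometer series")
    return raw.with_values((raw.values - cal.zero_offset) / cal.scale)


def jerk(accel: TimeSeries, config: AnalysisConfig) -> TimeSeries:
    """20 Hz zero-phase low-pass, then central-difference derivative (g/s)."""
    filt = lowpass(accel, config.lp_accel_cutoff)
    d = np.gradient(filt.values, 1.0 / accel.fs, axis=0)
    return accel.with_values(d)


# ---------------------------------------------------------------------------
# continuous wavelet transform

def morlet_cwt(x: np.ndarray, fs: float, freqs: np.ndarray,
               omega0: float = 6.0) -> np.ndarray:
    """Analytic Morlet CWT of ``x`` at the given frequencies (Hz).

    Returns complex coefficients of shape ``(len(freqs), len(x))``.  The
    wavelet is applied in the frequency domain as
    ``psi_hat(omega) = 2 exp(-(s omega - omega0)^2 / 2)`` for ``omega > 0``
    with scale ``s = omega0 / (2 pi f)``.  The amplitude normalization makes
    ``|W|`` equal to the envelope amplitude of a pure tone at its own
    frequency, so equal-amplitude tones at different frequencies produce
    equal peak power.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nfft = next_fast_len(2 * n)  # pad against circular wrap-around
    X = fft(x - x.mean(), nfft)
    omega = 2 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    out = np.empty((len(freqs), n), dtype=complex)
    pos = omega > 0
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        s = omega0 / (2 * np.pi * f)
        psi_hat = np.zeros(nfft)
        psi_hat[pos] = 2.0 * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        out[i] = ifft(X * psi_hat)[:n]
    return out


@dataclass
class BandPowerSeries:
    """Active-search-band wavelet power and dominant frequency over time."""

    t: np.ndarray
    power: np.ndarray  # mean |W|^2 over the band, per sample
    dominant_freq: np.ndarray  # band frequency with highest power, per sample
    band: tuple[float, float]
    freqs: np.ndarray = None  # full analysis grid (Hz)
    mean_spectrum: np.ndarray = None  # time-averaged |W|^2 per grid frequency


def cwt_band_power(jerk_x: TimeSeries, config: AnalysisConfig) -> BandPowerSeries:
    """Band power and dominant frequency of the pitch jerk channel."""
    if jerk_x.values.ndim != 1:
        raise ValueError("cwt_band_power expects a single channel (pitch jerk)")
    if jerk_x.duration < 2.0:
        raise ValueError("trace must be at least 2 s long")
    freqs = np.geomspace(config.cwt_f_lo, config.cwt_f_hi, config.cwt_voices)
    in_band = (freqs >= config.band_lo) & (freqs <= config.band_hi)
    if not np.any(in_band):
        raise ValueError("active-search band contains no grid frequency")
    W = morlet_cwt(jerk_x.values, jerk_x.fs, freqs, omega0=config.cwt_omega0)
    P = np.abs(W) ** 2
    band_p = P[in_band]
    return BandPowerSeries(
        t=jerk_x.times,
        power=band_p.mean(axis=0),
        dominant_freq=freqs[in_band][np.argmax(band_p, axis=0)],
        band=(config.band_lo, config.band_hi),
        freqs=freqs,
        mean_spectrum=P.mean(axis=1),
    )


# ---------------------------------------------------------------------------
# head height (Z - X moving median) and raised/lowered classification

def head_height_signal(accel: TimeSeries, config: AnalysisConfig) -> TimeSeries:
    """Moving-median Z minus moving-median X, per sample (units of g).

    Centered 1-s windows; edges use truncated windows.  Proxy for the head
    angle relative to the ground: larger values = head raised.
    """
    if accel.n_channels != 3:
        raise ValueError("expected a 3-channel accelerometer series")
    w = max(1, int(round(config.head_median_window * accel.fs)))
    if w > accel.n:
        raise ValueError("head_median_window longer than the trace")
    roll = lambda a: (
        pd.Series(a).rolling(w, center=True, min_periods=1).median().to_numpy()
    )
    d = roll(accel.values[:, 2]) - roll(accel.values[:, 0])
    return accel.with_values(d)


@dataclass
class GmmFit:
    """A 1-D Gaussian mixture fit, components sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: float
    k: int
    bic_by_k: dict[int, float] = None

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.weights = np.asarray(self.weights, float)[order]
        self.means = np.asarray(self.means, float)[order]
        self.sds = np.asarray(self.sds, float)[order]
        if np.any(self.sds <= 0):
            raise ValueError("component SDs must be positive")


def fit_head_state_threshold(pooled_d: np.ndarray, config: AnalysisConfig,
                             ks: tuple[int, ...] = (1, 2, 3, 4, 5),
                             ) -> tuple[GmmFit, float]:
    """Fit Gaussian mixtures to pooled Z-X samples; return fit and threshold.

    BIC is reported for every k in ``ks``, but the selected model size is
    ``config.gmm_k`` (default 3): in pooled head-height data the BIC drops
    substantially up to three components and only marginally beyond, and the
    three-component model has the behavioral raised/lowered interpretation.
    The raised threshold is ``mean - SD`` of the component with the largest
    mean; samples above it are classified head-raised.
    """
    d = np.asarray(pooled_d, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 1000:
        raise ValueError(f"need at least 1000 pooled samples, got {len(d)}")
    if np.ptp(d) == 0:
        raise ValueError("degenerate input: all pooled samples identical")
    if config.gmm_k not in ks:
        ks = tuple(sorted(set(ks) | {config.gmm_k}))
    X = d[:, None]
    bic_by_k: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            n_init=config.gmm_restarts if k == config.gmm_k else 2,
            random_state=config.rng_seed,
            covariance_type="full",
        ).fit(X)
        if not gm.converged_:
            raise RuntimeError(
                f"GMM with k={k} failed to converge after "
                f"{config.gmm_restarts} restarts"
            )
        bic_by_k[k] = float(gm.bic(X))
        fits[k] = gm
    gm = fits[config.gmm_k]
    fit = GmmFit(
        weights=gm.weights_,
        means=gm.means_[:, 0],
        sds=np.sqrt(gm.covariances_[:, 0, 0]),
        bic=bic_by_k[config.gmm_k],
        k=config.gmm_k,
        bic_by_k=bic_by_k,
    )
    threshold = float(fit.means[-1] - fit.sds[-1])
    return fit, threshold


@dataclass
class HeadStateSeries:
    """Per-sample head height d (g), threshold, and raised classification."""

    t: np.ndarray
    d: np.ndarray
    threshold: float
    raised: np.ndarray


def classify_head_state(d: TimeSeries, threshold: float) -> HeadStateSeries:
    return HeadStateSeries(
        t=d.times, d=d.values, threshold=float(threshold),
        raised=d.values > threshold,
    )
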