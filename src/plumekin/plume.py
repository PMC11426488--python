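"""Odor-sensor conditioning and plume-encounter detection.

A metal-oxide gas sensor reports odor concentration convolved with a slow
sensor response.  The processing chain is:

1. zero-phase low-pass (default 5 Hz) to strip broadband noise;
2. deconvolution with a difference-of-two-exponentials response kernel
   ``k(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / (tau_decay - tau_rise)``
   (unit area, tau_rise = 0.02 s, tau_decay = 10 s) via regularized
   frequency-domain division, which sharpens encounter transients back into
   near-impulses;
3. change detection on the cumulative sum of the deconvolved trace: at each
   sample, the ratio of the least-squares slope of the cumulative sum over
   the following 1 s to the slope over the preceding 1 s is formed, and an
   encounter onset is the first sample of every maximal run in which that
   ratio exceeds a threshold.

The cumulative sum is taken of the deconvolved signal shifted so its minimum
is zero (plus a small epsilon), which makes it strictly increasing: reverse
slopes are always positive and the ratio is well defined.  It also makes the
detector exactly invariant to any DC offset of the raw trace.

The threshold is a dimensionless slope ratio; it can be fixed in the config
or calibrated on event-free ("blank") recordings to a target false-positive
rate with :func:`calibrate_threshold`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import fft, ifft, next_fast_len

from .config import AnalysisConfig
from .timeseries import KeypointTrack, TimeSeries

__all__ = [
    "PlumeTrace",
    "PlumeEventList",
    "response_kernel",
    "convolve_kernel",
    "lowpass",
    "deconvolve",
    "slope_ratio",
    "detect_events",
    "calibrate_threshold",
    "filter_events",
    "preprocess_sensor",
    "read_events_csv",
    "write_events_csv",
]


# ---------------------------------------------------------------------------
# sensor response kernel


def response_kernel(tau_rise: float, tau_decay: float, fs: float,
                    support: float = 100.0) -> np.ndarray:
    """Unit-area difference-of-exponentials kernel sampled at ``fs``."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError(
            f"need 0 < tau_rise < tau_decay, got tau_rise={tau_rise}, tau_decay={tau_decay}"
        )
    t = np.arange(int(round(support * fs))) / fs
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    k /= k.sum() / fs  # unit area under continuous-time convention
    return k


def convolve_kernel(x: np.ndarray, kernel: np.ndarray, fs: float) -> np.ndarray:
    """Continuous-convention convolution ``(x * k)(t)``, truncated to len(x)."""
    return sps.fftconvolve(x, kernel)[: len(x)] / fs


# ---------------------------------------------------------------------------
# filtering and deconvolution


def lowpass(ts: TimeSeries, cutoff: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass with unit DC gain."""
    if cutoff >= ts.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {ts.fs / 2} Hz")
    sos = sps.butter(order, cutoff, fs=ts.fs, output="sos")
    vals = sps.sosfiltfilt(sos, ts.values, axis=0)
    return ts.with_values(vals)


def deconvolve(ts: TimeSeries, tau_rise: float, tau_decay: float,
               reg: float = 1e-10, kernel_support: float = 100.0,
               edge_pad: float = 5.0) -> TimeSeries:
    """Invert convolution with the response kernel by regularized FFT division.

    ``X_hat = Y conj(K) / (|K|^2 + reg * max|K|^2)`` (Tikhonov / Wiener with a
    flat noise floor).  ``reg`` trades noise amplification against sharpness;
    the default keeps the noiseless round trip below 1e-3 of signal range
    while bounding white-noise gain.

    The trace is edge-value padded by ``edge_pad`` seconds before the FFT:
    the inverse filter is differentiator-like, so the implicit step between a
    nonzero sensor baseline and the zero padding would otherwise deconvolve
    into huge boundary spikes.
    """
    x = ts.values
    if x.ndim != 1:
        raise ValueError("deconvolve expects a single-channel series")
    npad = int(round(edge_pad * ts.fs))
    xp = np.pad(x, npad, mode="edge")
    k = response_kernel(tau_rise, tau_decay, ts.fs, support=kernel_support)
    nfft = next_fast_len(len(xp) + len(k))
    K = fft(k, nfft) / ts.fs
    Y = fft(xp, nfft)
    lam = reg * np.max(np.abs(K)) ** 2
    out = ifft(Y * np.conj(K) / (np.abs(K) ** 2 + lam)).real
    out = out[npad: npad + len(x)]
    return ts.with_values(out)


@dataclass
class PlumeTrace:
    """Raw, low-passed, and deconvolved versions of one sensor trace."""

    raw: TimeSeries
    filtered: TimeSeries
    deconvolved: TimeSeries

    def __post_init__(self) -> None:
        if not (self.raw.n == self.filtered.n == self.deconvolved.n):
            raise ValueError("raw/filtered/deconvolved must share length")


def preprocess_sensor(raw: TimeSeries, config: AnalysisConfig) -> PlumeTrace:
    filt = lowpass(raw, config.lp_sensor_cutoff)
    deconv = deconvolve(
        filt, config.tau_rise, config.tau_decay,
        reg=config.deconv_reg, kernel_support=config.kernel_support,
    )
    return PlumeTrace(raw=raw, filtered=filt, deconvolved=deconv)


# ---------------------------------------------------------------------------
# slope-ratio change detection


def _ols_slope_weights(n: int, fs: float) -> np.ndarray:
    """Weights w such that w . y is the OLS slope of y against time (s)."""
    x = np.arange(n) / fs
    x = x - x.mean()
    return x / np.dot(x, x)


def slope_ratio(deconv: TimeSeries, config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Forward/reverse cumulative-sum slope ratio ``r(t)`` at every sample.

    Returns ``(t, r)`` where ``r`` is NaN wherever a full ``slope_window`` is
    not available on both sides.
    """
    x = deconv.values
    if x.ndim != 1:
        raise ValueError("slope_ratio expects a single-channel series")
    n = len(x)
    w = int(round(config.slope_window * deconv.fs))
    if n <= 2 * w:
        raise ValueError(
            f"trace too short: {n} samples, need more than {2 * w} "
            f"(2 x slope_window at fs={deconv.fs})"
        )
    c = np.cumsum(x - x.min() + config.cumsum_eps)
    wts = _ols_slope_weights(w, deconv.fs)
    # slope of C over windows starting at each sample: valid index i gives
    # window [i, i+w); direct sliding dot keeps this bit-comparable with a
    # per-window least-squares fit
    starts = np.correlate(c, wts, mode="valid")  # length n - w + 1
    r = np.full(n, np.nan)
    idx = np.arange(w, n - w + 1)
    s_f = starts[idx]          # window [t, t + w)
    s_r = starts[idx - w]      # window [t - w, t)
    r[idx] = s_f / s_r
    return deconv.times, r


@dataclass
class PlumeEventList:
    """Detected encounter onsets plus per-event filter outcomes."""

    onsets: np.ndarray  # s
    ratio_at_onset: np.ndarray
    distance_px: np.ndarray = field(default=None)
    retained: np.ndarray = field(default=None)
    reason: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.ratio_at_onset = np.asarray(self.ratio_at_onset, dtype=float)
        n = len(self.onsets)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.distance_px is None:
            self.distance_px = np.full(n, np.nan)
        self.distance_px = np.asarray(self.distance_px, dtype=float)
        if self.retained is None:
            self.retained = np.ones(n, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.reason is None:
            self.reason = [""] * n
        for arr in (self.ratio_at_onset, self.distance_px, self.retained):
            if len(arr) != n:
                raise ValueError("per-event arrays must share length")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def retained_onsets(self) -> np.ndarray:
        return self.onsets[self.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": self.onsets,
            "ratio": self.ratio_at_onset,
            "distance_px": self.distance_px,
            "retained": self.retained,
            "reason": self.reason,
        })


def detect_events(deconv: TimeSeries, config: AnalysisConfig,
                  threshold: float | None = None,
                  refine: bool = True) -> PlumeEventList:
    """Unfiltered encounter onsets from supra-threshold slope-ratio runs.

    Each maximal run of ``r(t) >= threshold`` triggers one event.  Because
    the forward slope window looks ``slope_window`` seconds ahead, the run
    starts up to a window *before* the underlying signal rise; with
    ``refine`` (default) the reported onset is the sample of the largest
    deconvolved-signal increase within the triggering forward window
    ``[run_start, run_start + slope_window]``, which pins the onset to the
    concentration rise itself.  ``refine=False`` reports the first
    supra-threshold sample.  ``ratio_at_onset`` is the peak ratio of the run.
    """
    thr = config.event_ratio_threshold if threshold is None else threshold
    t, r = slope_ratio(deconv, config)
    above = np.nan_to_num(r, nan=-np.inf) >= thr
    starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    ends = np.flatnonzero(above & ~np.concatenate((above[1:], [False])))
    if len(starts) == 0:
        return PlumeEventList(onsets=np.array([]), ratio_at_onset=np.array([]))
    x = deconv.values
    w = int(round(config.slope_window * deconv.fs))
    onsets_idx = []
    peaks = []
    for s, e in zip(starts, ends):
        peaks.append(np.nanmax(r[s:e + 1]))
        if refine:
            hi = min(len(x) - 1, s + w)
            dx = np.diff(x[s:hi + 1])
            onsets_idx.append(s + (int(np.argmax(dx)) + 1 if len(dx) else 0))
        else:
            onsets_idx.append(s)
    onsets_idx = np.asarray(onsets_idx)
    peaks = np.asarray(peaks)
    keep = np.concatenate(([True], np.diff(onsets_idx) > 0))  # dedupe
    return PlumeEventList(onsets=t[onsets_idx[keep]], ratio_at_onset=peaks[keep])


def calibrate_threshold(blank_traces: list[TimeSeries], config: AnalysisConfig,
                        target_fp_rate: float = 0.1,
                        margin: float = 1e-9) -> float:
    """Smallest slope-ratio threshold with blank event rate <= target (per min).

    ``blank_traces`` are deconvolved event-free recordings (task sessions
    without an animal, or pure sensor noise).  With ``target_fp_rate = 0``
    the threshold clears the largest observed ratio.
    """
    if not blank_traces:
        raise ValueError("at least one blank trace is required")
    ratios = []
    minutes = 0.0
    for ts in blank_traces:
        _, r = slope_ratio(ts, config)
        ratios.append(r[np.isfinite(r)])
        minutes += ts.duration / 60.0

    def rate(thr: float) -> float:
        n_events = 0
        for r in ratios:
            above = r >= thr
            n_events += int(np.sum(above & ~np.concatenate(([False], above[:-1]))))
        return n_events / minutes

    r_max = max(float(r.max()) for r in ratios)
    if target_fp_rate <= 0:
        return r_max + max(margin, 1e-3 * abs(r_max))
    if rate(r_max + margin) > target_fp_rate:  # pragma: no cover - defensive
        warnings.warn("blank traces contain events even at the maximal ratio")
    lo, hi = 1.0, r_max + 1.0
    for _ in range(60):  # bisection on the monotone event-rate curve
        mid = 0.5 * (lo + hi)
        if rate(mid) <= target_fp_rate:
            hi = mid
        else:
            lo = mid
    if rate(hi) > target_fp_rate:
        warnings.warn("calibration could not reach the target false-positive rate")
    return hi


def filter_events(events: PlumeEventList, keypoints: KeypointTrack,
                  port_xy: tuple[float, float],
                  in_arena: list[tuple[float, float]],
                  config: AnalysisConfig) -> PlumeEventList:
    """Apply edge, separation, and source-proximity filters to raw onsets.

    Order per event: (edge) onset must sit >= ``window_half`` inside an
    in-arena interval, with one video-frame margin so the full window has
    nearest-sample support on the coarsest stream; (separation) onset must
    follow the previous *retained* onset by more than
    ``min_event_separation`` (first-kept policy); (proximity) the body
    keypoint at the nearest frame must be more than ``min_source_distance``
    px from the port.  Only retained events anchor the separation chain.
    """
    n = len(events)
    retained = np.ones(n, dtype=bool)
    reason = [""] * n
    dist = np.full(n, np.nan)
    port = np.asarray(port_xy, dtype=float)

    body = keypoints.body.copy()
    bad = keypoints.body_p < config.likelihood_min
    body[bad] = np.nan

    last_kept = -np.inf
    for i, onset in enumerate(events.onsets):
        # distance of the animal from the source at onset (nearest frame;
        # fall back to the nearest confident frame within 0.5 s)
        j = int(keypoints.index_at(onset))
        xy = body[j]
        if np.any(np.isnan(xy)):
            half = int(round(0.5 * keypoints.fps))
            lo, hi = max(0, j - half), min(keypoints.n, j + half + 1)
            window = body[lo:hi]
            ok = np.flatnonzero(~np.isnan(window[:, 0]))
            if len(ok):
                xy = window[ok[np.argmin(np.abs(ok - (j - lo)))]]
        dist[i] = np.hypot(*(xy - port)) if not np.any(np.isnan(xy)) else np.nan

        frame = 1.0 / keypoints.fps
        inside = any(
            a + config.window_half + frame <= onset <= b - config.window_half - frame
            for a, b in in_arena
        )
        if not inside:
            retained[i], reason[i] = False, "edge"
            continue
        if onset - last_kept <= config.min_event_separation:
            retained[i], reason[i] = False, "separation"
            continue
        if np.isfinite(dist[i]) and dist[i] <= config.min_source_distance:
            retained[i], reason[i] = False, "proximity"
            continue
        last_kept = onset
    return PlumeEventList(
        onsets=events.onsets, ratio_at_onset=events.ratio_at_onset,
        distance_px=dist, retained=retained, reason=reason,
    )


def write_events_csv(events: PlumeEventList, path: str | Path) -> None:
    events.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_events_csv(path: str | Path) -> PlumeEventList:
    df = pd.read_csv(path)
    for col in ("onset_s", "ratio", "distance_px", "retained", "reason"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    reason = ["" if (isinstance(s, float) and np.isnan(s)) else str(s) for s in df["reason"]]
    return PlumeEventList(
        onsets=df["onset_s"].to_numpy(float),
        ratio_at_onset=df["ratio"].to_numpy(float),
        distance_px=df["distance_px"].to_numpy(float),
        retained=df["retained"].to_numpy(bool),
        reason=reason,
    )
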