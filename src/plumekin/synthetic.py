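"""Synthetic trial generator with exact ground truth.

The generator emulates the four per-trial data streams of the odor-source
localization task — odor-sensor voltage, 3-axis head accelerometer, overhead
keypoint tracking, and trial metadata — with scheduled plume-encounter times
and injected peri-encounter modulations, so that every stage of the analysis
pipeline can be validated against known truth.

World model
-----------
* Encounter times are *scheduled* (Poisson with a refractory period of twice
  the minimum event separation), not emergent from plume physics: the real
  plume is turbulent and unmodeled, and scheduled onsets give exact truth.
* Each encounter injects a short boxcar concentration pulse (fixed area,
  default dwell 0.3 s — an odor filament passage) which is convolved with
  the difference-of-exponentials sensor kernel; a slow sinusoidal drift
  (period >= 60 s, emulating temperature sensitivity of the metal-oxide
  sensor) and white Gaussian noise are added.
* The pitch (X) accelerometer channel carries a gravity baseline that
  depends on a raised/lowered head-state schedule (exponential dwell times)
  plus a head-pitch oscillation at a base frequency of 8 Hz.  Around each
  true onset the oscillation amplitude is multiplied by ``amp_boost_pre`` in
  the second before onset and ``amp_drop_post`` in the second after; its
  frequency gains ``freq_shift_post`` and the Z-channel baseline gains
  ``head_drop_post`` for 3 s after onset.  Z carries the complementary
  gravity projection plus an attenuated copy of the oscillation; Y is noise.
* The trajectory is a correlated random walk steered at the port: heading =
  angle-to-port + AR(1) circular noise whose SD is multiplied by
  ``heading_var_drop_post`` for 3 s after each onset.  Nose/neck/body are
  placed along the instantaneous heading at fixed segment lengths, with a
  sinusoidal head-yaw wobble on the nose.

In ``null_mode`` all modulation factors are 1 and shifts 0: encounters still
occur on the sensor but head motion and heading are statistically stationary
around them, which is the null the surrogate framework must reproduce.

Randomness uses numpy's PCG64 via ``default_rng``; per-trial generators are
spawned from a master ``SeedSequence`` so cohorts are reproducible and
platform independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import AnalysisConfig
from .plume import convolve_kernel, response_kernel
from .timeseries import KeypointTrack, TimeSeries, TrialRecord

__all__ = [
    "GroundTruth",
    "SyntheticConfig",
    "SyntheticTrial",
    "gen_events",
    "gen_sensor_trace",
    "gen_head_schedule",
    "gen_accel_trace",
    "gen_trajectory",
    "gen_trial",
    "gen_cohort",
    "gen_blank_sensor",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
]


@dataclass
class GroundTruth:
    """True encounter onsets and injected peri-encounter effect sizes."""

    true_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    amp_boost_pre: float = 1.5  # x pitch-oscillation amplitude in [-1, 0) s
    amp_drop_post: float = 0.6  # x amplitude in [0, 1) s
    freq_shift_post: float = 2.0  # Hz added to the oscillation in [0, 3) s
    head_drop_post: float = -0.15  # g added to the Z-X baseline in [0, 3) s
    heading_var_drop_post: float = 0.3  # x heading-noise SD in [0, 3) s
    null_mode: bool = False

    def __post_init__(self) -> None:
        self.true_onsets = np.sort(np.asarray(self.true_onsets, dtype=float))
        for name in ("amp_boost_pre", "amp_drop_post", "heading_var_drop_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive factor")
        if self.null_mode:
            ok = (
                self.amp_boost_pre == 1 and self.amp_drop_post == 1
                and self.heading_var_drop_post == 1
                and self.freq_shift_post == 0 and self.head_drop_post == 0
            )
            if not ok:
                raise ValueError("null_mode requires all factors 1 and shifts 0")

    @classmethod
    def null(cls) -> "GroundTruth":
        return cls(
            amp_boost_pre=1.0, amp_drop_post=1.0, freq_shift_post=0.0,
            head_drop_post=0.0, heading_var_drop_post=1.0, null_mode=True,
        )

    def with_onsets(self, onsets) -> "GroundTruth":
        return replace(self, true_onsets=np.asarray(onsets, dtype=float))


@dataclass
class SyntheticConfig:
    """World parameters of the generator (not analysis parameters).

    Scales follow the real apparatus: a 2 m x 0.9 m arena imaged at roughly
    300 px/m (so a 15 px source-distance filter is about one adult mouse
    body length), sensor events of ~0.1 V against ~5 mV sensor noise, and
    head-pitch oscillations of ~0.1 g at 8 Hz inside the 5-14 Hz
    active-search band.
    """

    duration: float = 90.0  # s per trial
    # encounter schedule
    events_per_trial: int | None = None  # exact count; None = Poisson
    mean_event_gap: float = 5.0  # s mean exponential gap beyond refractory
    # odor sensor
    pulse_area: float = 1.0  # V s concentration area per encounter
    pulse_width: float = 0.3  # s filament dwell (one sample => pure impulse)
    sensor_noise_sd: float = 0.005  # V
    drift_amplitude: float = 0.025  # V (= 5 x noise SD)
    drift_period: float = 60.0  # s
    sensor_baseline: float = 0.5  # V standing output; detector is DC-blind
    # accelerometer
    pitch_freq: float = 8.0  # Hz base head-pitch oscillation
    pitch_freq_wander_sd: float = 1.0  # Hz slow Ornstein-Uhlenbeck wander
    pitch_freq_wander_tau: float = 2.0  # s wander correlation time
    pitch_freq_raised_offset: float = -1.0  # Hz shift while head raised
    pitch_amp: float = 0.1  # g oscillation amplitude on X
    z_attenuation: float = 0.3  # fraction of the oscillation leaking into Z
    accel_noise_sd: float = 0.02  # g per channel
    x_lowered: float = 0.9
    z_lowered: float = 0.0  # d = Z - X = -0.9 g head down
    x_raised: float = 0.4
    z_raised: float = 0.7  # d = +0.3 g head up
    mean_raised_dwell: float = 4.0  # s
    mean_lowered_dwell: float = 8.0  # s
    baseline_smooth: float = 0.2  # s smoothing of state transitions
    # effect windows around each onset
    pre_boost_window: float = 1.0  # s before onset (amplitude boost)
    post_drop_window: float = 1.0  # s after onset (amplitude drop)
    post_shift_window: float = 3.0  # s after onset (freq/head/heading shifts)
    # arena and trajectory
    arena: tuple[float, float, float, float] = (0.0, 0.0, 600.0, 270.0)  # px
    port_region: tuple[float, float, float, float] = (350.0, 40.0, 560.0, 230.0)
    entry_xy: tuple[float, float] = (25.0, 135.0)
    run_speed: float = 60.0  # px/s (~0.2 m/s)
    heading_noise_sd: float = 40.0  # deg stationary SD of heading error
    heading_tau: float = 0.5  # s AR(1) correlation time of heading error
    segment_half: float = 4.0  # px body-to-midpoint = midpoint-to-neck
    head_length: float = 7.0  # px neck-to-nose
    yaw_amp: float = 25.0  # deg head-yaw wobble amplitude
    yaw_freq: float = 2.0  # Hz wobble frequency
    yaw_noise_sd: float = 5.0  # deg white yaw jitter
    dropout_fraction: float = 0.02  # frames with likelihood 0.5
    wall_margin: float = 12.0  # px reflection margin
    capture_radius: float = 25.0  # px; reaching the port restarts the run


@dataclass
class SyntheticTrial:
    trial: TrialRecord
    truth: GroundTruth


def as_seedseq(seed) -> np.random.SeedSequence:
    """Coerce an int or SeedSequence into a SeedSequence."""
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    return np.random.default_rng(seed)


def gen_events(config: AnalysisConfig, synth: SyntheticConfig, seed) -> np.ndarray:
    """Scheduled encounter onsets: Poisson with refractory 2 x min separation.

    Onsets keep a full peri-event window inside the trial.
    """
    rng = _rng(seed)
    refractory = 2.0 * config.min_event_separation
    lo, hi = config.window_half, synth.duration - config.window_half
    if hi <= lo:
        raise ValueError("trial too short for any event window")
    if synth.events_per_trial is not None:
        k = synth.events_per_trial
        for _ in range(1000):
            cand = np.sort(rng.uniform(lo, hi, size=k))
            if k < 2 or np.min(np.diff(cand)) > refractory:
                return cand
        raise ValueError(
            f"cannot place {k} events with {refractory} s refractory in "
            f"{hi - lo:.0f} s"
        )
    onsets = []
    t = lo + rng.exponential(synth.mean_event_gap)
    while t < hi:
        onsets.append(t)
        t += refractory + rng.exponential(synth.mean_event_gap)
    return np.asarray(onsets)


def gen_sensor_trace(true_onsets, config: AnalysisConfig, seed,
                     synth: SyntheticConfig | None = None) -> TimeSeries:
    """Odor-sensor voltage: pulses * kernel + slow drift + white noise."""
    synth = synth or SyntheticConfig()
    rng = _rng(seed)
    fs = config.fs_sensor
    n = int(round(synth.duration * fs))
    onsets = np.asarray(true_onsets, dtype=float)
    if np.any((onsets < 0) | (onsets > synth.duration)):
        raise ValueError("onset outside the trace duration")
    x = np.zeros(n)
    n_w = max(1, int(round(synth.pulse_width * fs)))
    for onset in onsets:
        i = int(round(onset * fs))
        j = min(n, i + n_w)
        # boxcar of fixed area: concentration pulse of finite dwell
        x[i:j] += synth.pulse_area * fs / n_w
    k = response_kernel(config.tau_rise, config.tau_decay, fs,
                        support=config.kernel_support)
    v = convolve_kernel(x, k, fs)
    t = np.arange(n) / fs
    if synth.drift_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        v = v + synth.drift_amplitude * np.sin(2 * np.pi * t / synth.drift_period + phase)
    if synth.sensor_noise_sd:
        v = v + rng.normal(0.0, synth.sensor_noise_sd, size=n)
    return TimeSeries(0.0, fs, v + synth.sensor_baseline)


def gen_blank_sensor(config: AnalysisConfig, seed,
                     synth: SyntheticConfig | None = None,
                     duration: float | None = None) -> TimeSeries:
    """Event-free sensor recording (plume rig noise + drift, no encounters)."""
    synth = synth or SyntheticConfig()
    if duration is not None:
        synth = replace(synth, duration=duration)
    return gen_sensor_trace([], config, seed, synth)


def gen_head_schedule(synth: SyntheticConfig, seed) -> list[tuple[float, float, str]]:
    """Alternating raised/lowered epochs with exponential dwell times."""
    rng = _rng(seed)
    out = []
    t = 0.0
    state = "raised" if rng.random() < 0.5 else "lowered"
    while t < synth.duration:
        dwell = rng.exponential(
            synth.mean_raised_dwell if state == "raised" else synth.mean_lowered_dwell
        )
        dwell = max(dwell, 0.2)
        out.append((t, min(t + dwell, synth.duration), state))
        t += dwell
        state = "lowered" if state == "raised" else "raised"
    return out


def _onset_window_mask(t: np.ndarray, onsets: np.ndarray,
                       start: float, stop: float) -> np.ndarray:
    """Boolean mask of samples with t - onset in [start, stop) for any onset."""
    m = np.zeros(len(t), dtype=bool)
    for onset in onsets:
        m |= (t >= onset + start) & (t < onset + stop)
    return m


def gen_accel_trace(true_onsets, head_schedule, config: AnalysisConfig, seed,
                    truth: GroundTruth | None = None,
                    synth: SyntheticConfig | None = None) -> TimeSeries:
    """3-channel accelerometer in g with peri-encounter pitch modulations."""
    synth = synth or SyntheticConfig()
    truth = truth or GroundTruth.null()
    rng = _rng(seed)
    fs = config.fs_accel
    n = int(round(synth.duration * fs))
    t = np.arange(n) / fs
    onsets = np.asarray(true_onsets, dtype=float)

    if head_schedule is None:
        head_schedule = [(0.0, synth.duration, "raised")]
    covered = max(b for _, b, _ in head_schedule)
    if covered < synth.duration - 1e-9:
        raise ValueError("head-state schedule does not cover the trace")
    raised = np.zeros(n, dtype=bool)
    for a, b, state in head_schedule:
        if state == "raised":
            raised[(t >= a) & (t < b)] = True

    x_base = np.where(raised, synth.x_raised, synth.x_lowered)
    z_base = np.where(raised, synth.z_raised, synth.z_lowered)
    if truth.head_drop_post:
        post3 = _onset_window_mask(t, onsets, 0.0, synth.post_shift_window)
        z_base = z_base + truth.head_drop_post * post3
    sm = synth.baseline_smooth * fs
    if sm > 0:  # heads move continuously; soften schedule steps
        x_base = gaussian_filter1d(x_base.astype(float), sm)
        z_base = gaussian_filter1d(z_base.astype(float), sm)

    freq = np.full(n, synth.pitch_freq)
    if synth.pitch_freq_wander_sd > 0:
        # slow OU wander: the head-pitch rhythm is not a pure tone, its
        # dominant frequency has a broad distribution
        a = np.exp(-1.0 / (synth.pitch_freq_wander_tau * fs))
        innov = rng.normal(0.0, synth.pitch_freq_wander_sd, size=n)
        fw = np.empty(n)
        fw[0] = innov[0]
        c = np.sqrt(1 - a * a)
        for i in range(1, n):
            fw[i] = a * fw[i - 1] + c * innov[i]
        freq = freq + fw
    if synth.pitch_freq_raised_offset:
        freq = freq + synth.pitch_freq_raised_offset * raised
    if truth.freq_shift_post:
        freq += truth.freq_shift_post * _onset_window_mask(
            t, onsets, 0.0, synth.post_shift_window
        )
    amp = np.full(n, synth.pitch_amp)
    amp[_onset_window_mask(t, onsets, -synth.pre_boost_window, 0.0)] *= truth.amp_boost_pre
    amp[_onset_window_mask(t, onsets, 0.0, synth.post_drop_window)] *= truth.amp_drop_post
    phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    osc = amp * np.sin(phase)

    noise = rng.normal(0.0, synth.accel_noise_sd, size=(n, 3))
    vals = np.column_stack([
        x_base + osc + noise[:, 0],
        noise[:, 1],
        z_base + synth.z_attenuation * osc + noise[:, 2],
    ])
    return TimeSeries(0.0, fs, vals)


def _rotate_img(u: np.ndarray, psi_deg: np.ndarray) -> np.ndarray:
    """Rotate image-coordinate vectors by psi (deg), CCW-on-screen positive."""
    p = np.radians(psi_deg)
    c, s = np.cos(p), np.sin(p)
    return np.stack([c * u[:, 0] + s * u[:, 1], -s * u[:, 0] + c * u[:, 1]], axis=1)


def gen_trajectory(config: AnalysisConfig, truth: GroundTruth, seed,
                   synth: SyntheticConfig | None = None,
                   true_onsets=None) -> tuple[KeypointTrack, tuple[float, float]]:
    """Correlated random walk toward the port, with keypoints and likelihoods.

    Heading = angle-to-port + AR(1) circular noise; the noise SD is
    multiplied by ``heading_var_drop_post`` for ``post_shift_window`` seconds
    after each true onset.
    """
    synth = synth or SyntheticConfig()
    rng = _rng(seed)
    x0, y0, x1, y1 = synth.arena
    if x1 <= x0 or y1 <= y0:
        raise ValueError("arena dimensions must be positive")
    px0, py0, px1, py1 = synth.port_region
    port = np.array([rng.uniform(px0, px1), rng.uniform(py0, py1)])
    if not (x0 <= port[0] <= x1 and y0 <= port[1] <= y1):
        raise ValueError("port outside arena")
    onsets = np.asarray(
        true_onsets if true_onsets is not None else truth.true_onsets, dtype=float
    )

    fps = config.fps_video
    dt = 1.0 / fps
    n = int(round(synth.duration * fps))
    t = np.arange(n) * dt

    sd = np.full(n, np.radians(synth.heading_noise_sd))
    sd[_onset_window_mask(t, onsets, 0.0, synth.post_shift_window)] *= truth.heading_var_drop_post
    rho = np.exp(-dt / synth.heading_tau)
    innov = rng.normal(size=n)

    pos = np.empty((n, 2))
    heading = np.empty(n)  # y-up frame, rad
    p = np.array(synth.entry_xy, dtype=float)
    eta = sd[0] * innov[0]
    margin = synth.wall_margin
    for i in range(n):
        to_port = port - p
        ang_port = np.arctan2(-to_port[1], to_port[0])  # y-up
        th = ang_port + eta
        pos[i] = p
        heading[i] = th
        step = synth.run_speed * dt * np.array([np.cos(th), -np.sin(th)])
        p = p + step
        p[0] = np.clip(p[0], x0 + margin, x1 - margin)
        p[1] = np.clip(p[1], y0 + margin, y1 - margin)
        if np.hypot(*(port - p)) < synth.capture_radius:
            # source found: the animal is returned to the entry and the
            # search continues (a trial is a session of successive passes)
            p = np.array(synth.entry_xy, dtype=float) + rng.normal(0, 3, 2)
        if i + 1 < n:
            eta = rho * eta + np.sqrt(1 - rho * rho) * sd[i + 1] * innov[i + 1]

    u = np.stack([np.cos(heading), -np.sin(heading)], axis=1)  # image coords
    body = pos - synth.segment_half * u
    neck = pos + synth.segment_half * u
    psi = synth.yaw_amp * np.sin(2 * np.pi * synth.yaw_freq * t + rng.uniform(0, 2 * np.pi))
    psi = psi + rng.normal(0.0, synth.yaw_noise_sd, size=n)
    nose = neck + synth.head_length * _rotate_img(u, psi)

    likes = np.ones((n, 3))
    n_drop = int(round(synth.dropout_fraction * n))
    if n_drop:
        for j in range(3):
            likes[rng.choice(n, size=n_drop, replace=False), j] = 0.5

    track = KeypointTrack(
        fps=fps, nose=nose, neck=neck, body=body,
        nose_p=likes[:, 0], neck_p=likes[:, 1], body_p=likes[:, 2],
    )
    return track, (float(port[0]), float(port[1]))


def gen_trial(config: AnalysisConfig, truth: GroundTruth, seed,
              synth: SyntheticConfig | None = None,
              trial_id: str | None = None) -> SyntheticTrial:
    """Assemble one synthetic trial; deterministic given (config, truth, seed)."""
    synth = synth or SyntheticConfig()
    ss = as_seedseq(seed)
    s_events, s_sensor, s_sched, s_accel, s_traj = ss.spawn(5)
    onsets = gen_events(config, synth, s_events)
    truth = truth.with_onsets(onsets)
    sensor = gen_sensor_trace(onsets, config, s_sensor, synth)
    schedule = gen_head_schedule(synth, s_sched)
    accel = gen_accel_trace(onsets, schedule, config, s_accel, truth, synth)
    track, port = gen_trajectory(config, truth, s_traj, synth, true_onsets=onsets)
    trial = TrialRecord(
        trial_id=trial_id or f"trial{seed if isinstance(seed, int) else ''}",
        sensor=sensor, accel=accel, keypoints=track,
        port_xy=port, arena_bounds=synth.arena,
        in_arena=[(0.0, synth.duration)],
    )
    return SyntheticTrial(trial=trial, truth=truth)


def gen_cohort(config: AnalysisConfig, truth: GroundTruth, n_trials: int, seed,
               synth: SyntheticConfig | None = None) -> list[SyntheticTrial]:
    """Independent per-trial seeds spawned from one master seed."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    children = as_seedseq(seed).spawn(n_trials)
    return [
        gen_trial(config, truth, child, synth, trial_id=f"trial{i:03d}")
        for i, child in enumerate(children)
    ]


def write_ground_truth_csv(trials: list[SyntheticTrial], path: str | Path) -> None:
    truth = trials[0].truth
    scalars = {
        "amp_boost_pre": truth.amp_boost_pre,
        "amp_drop_post": truth.amp_drop_post,
        "freq_shift_post": truth.freq_shift_post,
        "head_drop_post": truth.head_drop_post,
        "heading_var_drop_post": truth.heading_var_drop_post,
        "null_mode": truth.null_mode,
    }
    with open(path, "w") as fh:
        for k, v in scalars.items():
            fh.write(f"# {k}={v}\n")
        fh.write("trial_id,onset_s\n")
        for st in trials:
            for onset in st.truth.true_onsets:
                fh.write(f"{st.trial.trial_id},{onset:.6f}\n")


def read_ground_truth_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            k, v = line[1:].strip().split("=", 1)
            try:
                meta[k] = float(v)
            except ValueError:
                meta[k] = v == "True"
        else:
            body.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)))
    return df, meta
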