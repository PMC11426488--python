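"""Analysis configuration.

Every numeric knob of the pipeline lives in :class:`AnalysisConfig` so a run
is fully described by one YAML file.  Defaults follow the published analysis
protocol where one is stated (filter cutoffs, deconvolution time constants,
the 5-14 Hz active-search band, event filters, window geometry) and are
declared package defaults otherwise (sampling rates, wavelet grid,
regularization constants).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    # stream geometry (acquisition rates are hardware choices, not protocol
    # constants; all downstream math is rate-parameterized)
    fs_sensor: float = 100.0  # Hz, odor-sensor channel
    fs_accel: float = 100.0  # Hz, 3-axis accelerometer
    fps_video: float = 30.0  # frames/s, overhead camera

    # odor-sensor conditioning
    lp_sensor_cutoff: float = 5.0  # Hz zero-phase low-pass before deconvolution
    tau_rise: float = 0.02  # s, sensor response rise time constant
    tau_decay: float = 10.0  # s, sensor response decay time constant
    deconv_reg: float = 1e-10  # Tikhonov regularizer, relative to max |K|^2
    kernel_support: float = 100.0  # s, sampled kernel length (>= 5 tau_decay)

    # plume-event detection (cumulative-sum slope-ratio)
    event_ratio_threshold: float = 1.3  # forward/reverse slope ratio
    slope_window: float = 1.0  # s, OLS slope segment on either side
    cumsum_eps: float = 1e-5  # baseline increment keeping reverse slope > 0
    min_event_separation: float = 5.0  # s, closer events dropped (first kept)
    min_source_distance: float = 15.0  # px, ~one adult mouse body length
    window_half: float = 5.0  # s, peri-event window half width

    # accelerometer / head motion
    lp_accel_cutoff: float = 20.0  # Hz low-pass before differentiation to jerk
    band_lo: float = 5.0  # Hz, active-search band lower edge
    band_hi: float = 14.0  # Hz, active-search band upper edge
    cwt_f_lo: float = 0.5  # Hz, wavelet frequency grid lower edge
    cwt_f_hi: float = 25.0  # Hz, wavelet frequency grid upper edge
    cwt_voices: int = 48  # log-spaced frequencies on the grid
    cwt_omega0: float = 6.0  # Morlet center frequency (rad)
    head_median_window: float = 1.0  # s, moving median for the Z-X signal
    gmm_k: int = 3  # mixture size used for the head-raised threshold
    gmm_restarts: int = 10  # EM restarts

    # kinematics
    likelihood_min: float = 0.9  # keypoints below this confidence are masked
    body_angle_forward: bool = True  # heading = midpoint - body (see docs)
    speed_smooth_window: float = 0.5  # s, boxcar on the speed trace

    # peri-event statistics
    bin_width: float = 1.0  # s, KS-comparison bins tiling [-5, 5)
    angle_mean_window: float = 3.0  # s, before/after circular-mean periods
    random_exclusion: float = 1.0  # s, surrogate t=0 keep-out around onsets
    crossing_rate_window: float = 0.5  # s, rolling 0-deg crossing-rate window

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        durations = (
            "tau_rise", "tau_decay", "slope_window", "min_event_separation",
            "window_half", "bin_width", "angle_mean_window", "random_exclusion",
            "head_median_window", "crossing_rate_window", "kernel_support",
            "speed_smooth_window",
        )
        for name in durations:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("fs_sensor", "fs_accel", "fps_video"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.tau_rise < self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError(
                f"band_lo < band_hi required, got band_lo={self.band_lo}, "
                f"band_hi={self.band_hi}"
            )
        if self.band_hi >= self.fs_accel / 2:
            raise ValueError("band_hi must be below the accelerometer Nyquist rate")
        if self.lp_sensor_cutoff >= self.fs_sensor / 2:
            raise ValueError("lp_sensor_cutoff must be below the sensor Nyquist rate")
        if self.lp_accel_cutoff >= self.fs_accel / 2:
            raise ValueError("lp_accel_cutoff must be below the accelerometer Nyquist rate")
        if not 0 <= self.likelihood_min <= 1:
            raise ValueError(f"likelihood_min must be in [0, 1], got {self.likelihood_min}")
        if not 0 < self.cwt_f_lo < self.cwt_f_hi:
            raise ValueError("cwt_f_lo < cwt_f_hi required")
        if self.cwt_voices < 2:
            raise ValueError("cwt_voices must be at least 2")
        if self.event_ratio_threshold <= 0:
            raise ValueError("event_ratio_threshold must be positive")
        if self.min_source_distance < 0:
            raise ValueError("min_source_distance must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML; omitted fields use defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return AnalysisConfig.from_dict(data)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
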