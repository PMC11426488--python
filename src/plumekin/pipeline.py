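"""End-to-end per-trial and cohort analysis.

Chains the stages: sensor conditioning and plume-event detection -> event
filtering -> head-motion spectral series -> keypoint kinematics -> peri-event
window extraction with surrogate nulls -> per-bin KS grid and paired
circular tests.  This is the library core behind the command line; all
randomness is seeded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import headmotion as hm
from . import kinematics as kin
from . import perievent as pe
from . import plume
from .config import AnalysisConfig
from .synthetic import SyntheticTrial, as_seedseq
from .timeseries import TrialRecord

__all__ = ["TrialAnalysis", "CohortResult", "analyze_trial",
           "analyze_cohort", "pool_and_test", "detect_trial_events", "BIN_PARAMS"]

#: the four parameters compared real-vs-random per 1-s bin
BIN_PARAMS = ("band_power", "head_height", "dominant_freq", "crossing_z")


@dataclass
class TrialAnalysis:
    """Derived series and peri-event windows for one trial."""

    trial_id: str
    events: plume.PlumeEventList
    band_power: pe.PeriEventSet = None
    head_height: pe.PeriEventSet = None
    dominant_freq: pe.PeriEventSet = None
    body_angle: pe.PeriEventSet = None
    head_yaw: pe.PeriEventSet = None
    yaw_crossings_real: list = field(default_factory=list)
    yaw_crossings_random: list = field(default_factory=list)


@dataclass
class CohortResult:
    """Pooled peri-event comparisons for a cohort of trials."""

    n_trials: int
    n_events: int
    bin_tables: dict  # parameter -> BinComparison
    body_angle_R: pe.PairedRResult
    body_angle_R_random: pe.PairedRResult
    head_yaw_R: pe.PairedRResult = None
    head_yaw_R_random: pe.PairedRResult = None
    crossing_rate_real: tuple = None
    crossing_rate_random: tuple = None
    trials: list = None


def detect_trial_events(trial: TrialRecord, config: AnalysisConfig,
                        threshold: float | None = None) -> plume.PlumeEventList:
    """Sensor conditioning, slope-ratio detection, and event filtering."""
    tr = plume.preprocess_sensor(trial.sensor, config)
    raw_events = plume.detect_events(tr.deconvolved, config, threshold=threshold)
    return plume.filter_events(
        raw_events, trial.keypoints, trial.port_xy, trial.in_arena, config
    )


def analyze_trial(trial: TrialRecord, config: AnalysisConfig, seed,
                  events: plume.PlumeEventList | None = None,
                  threshold: float | None = None) -> TrialAnalysis | None:
    """All peri-event windows for one trial; None if no retained events."""
    if events is None:
        events = detect_trial_events(trial, config, threshold=threshold)
    if not np.any(events.retained):
        return None
    seeds = as_seedseq(seed).spawn(5)

    # head motion: pitch jerk -> band power + dominant frequency; Z-X height
    j = hm.jerk(trial.accel, config)
    bp = hm.cwt_band_power(j.channel(0), config)
    bp_ts = trial.accel.with_values(bp.power)
    df_ts = trial.accel.with_values(bp.dominant_freq)
    d_ts = hm.head_height_signal(trial.accel, config)

    # kinematics
    masked = kin.mask_low_likelihood(trial.keypoints, config.likelihood_min)
    ba = kin.body_angle(masked, trial.port_xy, forward=config.body_angle_forward)
    yaw = kin.head_yaw(masked)
    crossings = kin.zero_crossings(yaw)

    out = TrialAnalysis(trial_id=trial.trial_id, events=events)
    arena = trial.in_arena
    out.band_power = pe.build_peri_event_set(bp_ts, events, arena, config, seeds[0])
    out.head_height = pe.build_peri_event_set(d_ts, events, arena, config, seeds[1])
    out.dominant_freq = pe.build_peri_event_set(df_ts, events, arena, config, seeds[2])
    out.body_angle = pe.build_peri_event_set(ba, events, arena, config, seeds[3])
    out.head_yaw = pe.build_peri_event_set(yaw, events, arena, config, seeds[4])
    out.yaw_crossings_real = pe.crossing_windows(
        crossings, out.head_yaw.real_t0, config.window_half
    )
    out.yaw_crossings_random = pe.crossing_windows(
        crossings, out.head_yaw.random_t0, config.window_half
    )
    return out


def analyze_cohort(trials, config: AnalysisConfig, seed,
                   threshold: float | None = None,
                   use_true_onsets: bool = False,
                   keep_trials: bool = False) -> CohortResult:
    """Pool per-trial peri-event windows and run the group comparisons.

    ``trials`` may be TrialRecords or SyntheticTrials.  With
    ``use_true_onsets`` the generator's ground-truth onsets stand in for the
    detector (useful to isolate downstream stages).
    """
    child = as_seedseq(seed).spawn(len(trials))
    analyses = []
    for st, s in zip(trials, child):
        trial = st.trial if isinstance(st, SyntheticTrial) else st
        events = None
        if use_true_onsets:
            if not isinstance(st, SyntheticTrial):
                raise ValueError("use_true_onsets requires SyntheticTrials")
            onsets = st.truth.true_onsets
            if len(onsets) == 0:
                continue
            events = plume.PlumeEventList(
                onsets=onsets, ratio_at_onset=np.full(len(onsets), np.nan)
            )
            events = plume.filter_events(
                events, trial.keypoints, trial.port_xy, trial.in_arena, config
            )
        a = analyze_trial(trial, config, s, events=events, threshold=threshold)
        if a is not None:
            analyses.append(a)
    if not analyses:
        raise ValueError("no trial produced any retained event")
    return pool_and_test(analyses, config, keep_trials=keep_trials)


def pool_and_test(analyses: list[TrialAnalysis], config: AnalysisConfig,
                  keep_trials: bool = False) -> CohortResult:
    """Pool per-trial peri-event windows and run the group comparisons."""
    pooled = {
        name: pe.concat_sets([getattr(a, name) for a in analyses])
        for name in ("band_power", "head_height", "dominant_freq",
                     "body_angle", "head_yaw")
    }

    bin_tables = {}
    for name in ("band_power", "head_height", "dominant_freq"):
        s = pooled[name]
        rm, labels = pe.bin_means(s.real, s.time_axis, config.bin_width,
                                  config.window_half)
        sm, _ = pe.bin_means(s.random, s.time_axis, config.bin_width,
                             config.window_half)
        bin_tables[name] = pe.ks_per_bin(rm, sm, labels)

    # crossing-rate z curves and their per-bin comparison
    real_cross = [c for a in analyses for c in a.yaw_crossings_real]
    rand_cross = [c for a in analyses for c in a.yaw_crossings_random]
    dt = 1.0 / config.fps_video
    cr_real = pe.zscored_crossing_rate(real_cross, config, dt=dt)
    cr_rand = pe.zscored_crossing_rate(rand_cross, config, dt=dt)
    axis = cr_real[0]
    rm, labels = pe.bin_means(cr_real[5], axis, config.bin_width, config.window_half)
    sm, _ = pe.bin_means(cr_rand[5], axis, config.bin_width, config.window_half)
    bin_tables["crossing_z"] = pe.ks_per_bin(rm, sm, labels)

    res = CohortResult(
        n_trials=len(analyses),
        n_events=int(pooled["band_power"].real.shape[0]),
        bin_tables=bin_tables,
        body_angle_R=pe.paired_R_test(pooled["body_angle"], config, "real"),
        body_angle_R_random=pe.paired_R_test(pooled["body_angle"], config, "random"),
        head_yaw_R=pe.paired_R_test(pooled["head_yaw"], config, "real"),
        head_yaw_R_random=pe.paired_R_test(pooled["head_yaw"], config, "random"),
        crossing_rate_real=cr_real[:5],
        crossing_rate_random=cr_rand[:5],
        trials=analyses if keep_trials else None,
    )
    return res
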