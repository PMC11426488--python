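"""Peri-encounter windows, surrogate nulls, and the statistical comparisons.

Real trajectories are the [-5, +5] s windows of a series around retained
encounter onsets.  Random (surrogate) trajectories are windows of the same
size whose t = 0 is drawn uniformly from in-arena time with full window
support, excluding +-1 s around any real onset; one surrogate is drawn per
real event per trial, so each animal contributes equally to both
distributions.  Comparisons follow the published procedure: per-trajectory
means within 1-s bins compared real-vs-random by two-sample KS test per bin
(no multiple-testing correction; the per-bin grid is the result), and
circular before/after comparisons via the resultant-vector strength R with
a paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .config import AnalysisConfig
from .kinematics import AngleSeries, wrap_deg
from .plume import PlumeEventList
from .timeseries import TimeSeries

__all__ = [
    "PeriEventSet",
    "BinComparison",
    "write_results_csv",
    "read_results_csv",
    "extract_real_windows",
    "sample_random_windows",
    "build_peri_event_set",
    "bin_means",
    "ks_per_bin",
    "ks_per_bin_permutation",
    "circular_mean_R",
    "angle_deviation_distributions",
    "paired_R_test",
    "zscored_crossing_rate",
    "crossing_windows",
]


@dataclass
class PeriEventSet:
    """Aligned peri-event rows for real events and random surrogates.

    ``real`` and ``random`` have one row per event/surrogate on the shared
    ``time_axis`` (t = 0 at onset).  ``sort_key`` is the animal-to-source
    distance at onset, used only for display ordering.
    """

    time_axis: np.ndarray
    real: np.ndarray
    random: np.ndarray = None
    sort_key: np.ndarray = None
    real_t0: np.ndarray = None
    random_t0: np.ndarray = None

    def __post_init__(self) -> None:
        if self.random is not None and self.random.shape[1] != len(self.time_axis):
            raise ValueError("real and random rows must share the time axis")


def _series_arrays(series) -> tuple[np.ndarray, float, float]:
    """(values-with-NaN, fs, t0) for a TimeSeries or AngleSeries."""
    if isinstance(series, AngleSeries):
        return series.angle, series.fps, series.t0
    if isinstance(series, TimeSeries):
        if series.values.ndim != 1:
            raise ValueError("peri-event extraction expects a single channel")
        return series.values, series.fs, series.t0
    raise TypeError(f"unsupported series type {type(series)!r}")


def _window_rows(values: np.ndarray, fs: float, t0: float,
                 centers: np.ndarray, time_axis: np.ndarray) -> np.ndarray:
    """Nearest-sample lookup of ``values`` at centers[:,None] + time_axis."""
    tt = np.asarray(centers)[:, None] + time_axis[None, :]
    idx = np.rint((tt - t0) * fs).astype(int)
    if np.any(idx < 0) or np.any(idx >= len(values)):
        raise ValueError("event window extends beyond the recording edge")
    return values[idx]


def _time_axis(fs: float, window_half: float) -> np.ndarray:
    m = int(round(window_half * fs))
    return np.arange(-m, m + 1) / fs


def extract_real_windows(series, events: PlumeEventList,
                         config: AnalysisConfig) -> PeriEventSet:
    """One aligned row per retained event (hard error at recording edges)."""
    values, fs, t0 = _series_arrays(series)
    axis = _time_axis(fs, config.window_half)
    onsets = events.retained_onsets
    rows = _window_rows(values, fs, t0, onsets, axis)
    return PeriEventSet(
        time_axis=axis, real=rows,
        sort_key=events.distance_px[events.retained], real_t0=onsets,
    )


def sample_random_windows(series, events: PlumeEventList,
                          in_arena: list[tuple[float, float]],
                          config: AnalysisConfig, seed) -> PeriEventSet:
    """Surrogate rows: one per retained real event, t=0 uniform in-arena.

    Candidate t = 0 times must have full [-window_half, +window_half]
    support inside an in-arena interval and must not fall within
    ``random_exclusion`` of any real onset; real onsets may still appear
    elsewhere inside the surrogate window.
    """
    values, fs, t0 = _series_arrays(series)
    axis = _time_axis(fs, config.window_half)
    n_draw = int(np.sum(events.retained))
    grid = t0 + np.arange(len(values)) / fs
    ok = np.zeros(len(grid), dtype=bool)
    for a, b in in_arena:
        ok |= (grid >= a + config.window_half) & (grid <= b - config.window_half)
    # window support against the recording itself
    m = int(round(config.window_half * fs))
    ok[:m] = False
    ok[len(grid) - m:] = False
    for onset in events.onsets[events.retained]:
        ok &= np.abs(grid - onset) >= config.random_exclusion
    cand = grid[ok]
    if len(cand) == 0:
        raise ValueError("no admissible surrogate onset times")
    rng = np.random.default_rng(seed)
    centers = rng.choice(cand, size=n_draw, replace=True)
    rows = _window_rows(values, fs, t0, centers, axis)
    return PeriEventSet(time_axis=axis, real=np.empty((0, len(axis))),
                        random=rows, random_t0=centers)


def build_peri_event_set(series, events: PlumeEventList,
                         in_arena: list[tuple[float, float]],
                         config: AnalysisConfig, seed) -> PeriEventSet:
    """Real and surrogate windows of one series for one trial."""
    real = extract_real_windows(series, events, config)
    rand = sample_random_windows(series, events, in_arena, config, seed)
    return PeriEventSet(
        time_axis=real.time_axis, real=real.real, random=rand.random,
        sort_key=real.sort_key, real_t0=real.real_t0, random_t0=rand.random_t0,
    )


def concat_sets(sets: list[PeriEventSet]) -> PeriEventSet:
    """Pool per-trial PeriEventSets (shared time axis) into a cohort set."""
    axis = sets[0].time_axis
    for s in sets[1:]:
        if len(s.time_axis) != len(axis):
            raise ValueError("cannot pool sets with different time axes")
    cat = lambda parts: np.concatenate([p for p in parts if p is not None and len(p)]) \
        if any(p is not None and len(p) for p in parts) else None
    return PeriEventSet(
        time_axis=axis,
        real=np.vstack([s.real for s in sets]),
        random=np.vstack([s.random for s in sets if s.random is not None]),
        sort_key=cat([s.sort_key for s in sets]),
        real_t0=cat([s.real_t0 for s in sets]),
        random_t0=cat([s.random_t0 for s in sets]),
    )


def bin_means(rows: np.ndarray, time_axis: np.ndarray, bin_width: float,
              window_half: float) -> tuple[np.ndarray, list[str]]:
    """Per-row means within bins tiling [-window_half, window_half).

    Missing (NaN) samples are excluded; an all-missing bin stays NaN.
    """
    n_bins = int(round(2 * window_half / bin_width))
    if abs(n_bins * bin_width - 2 * window_half) > 1e-9:
        raise ValueError("bin_width must divide the full window")
    edges = -window_half + bin_width * np.arange(n_bins + 1)
    out = np.full((rows.shape[0], n_bins), np.nan)
    labels = []
    for b in range(n_bins):
        sel = (time_axis >= edges[b]) & (time_axis < edges[b + 1])
        with np.errstate(invalid="ignore"):
            out[:, b] = np.nanmean(rows[:, sel], axis=1)
        lo, hi = edges[b], edges[b + 1]
        fmt = lambda v: f"{v:g}"
        labels.append(f"{fmt(lo)} to {fmt(hi)}")
    return out, labels


@dataclass
class BinComparison:
    """Per-bin real-vs-random comparison (the Table-1-shaped grid)."""

    labels: list[str]
    ks_stat: np.ndarray
    p_value: np.ndarray
    n_real: np.ndarray
    n_random: np.ndarray
    real_mean: np.ndarray
    random_mean: np.ndarray


def ks_per_bin(real_means: np.ndarray, random_means: np.ndarray,
               labels: list[str], min_n: int = 5,
               mode: str = "asymp") -> BinComparison:
    """Two-sample KS test per bin on per-trajectory means."""
    n_bins = real_means.shape[1]
    ks = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    nr = np.zeros(n_bins, dtype=int)
    ns = np.zeros(n_bins, dtype=int)
    rm = np.full(n_bins, np.nan)
    sm = np.full(n_bins, np.nan)
    for b in range(n_bins):
        a = real_means[:, b]
        c = random_means[:, b]
        a, c = a[np.isfinite(a)], c[np.isfinite(c)]
        nr[b], ns[b] = len(a), len(c)
        if len(a):
            rm[b] = a.mean()
        if len(c):
            sm[b] = c.mean()
        if len(a) < min_n or len(c) < min_n:
            continue  # insufficient data: flagged by NaN p, not fatal
        if np.array_equal(np.sort(a), np.sort(c)):
            ks[b], p[b] = 0.0, 1.0
            continue
        res = sstats.ks_2samp(a, c, method=mode)
        ks[b], p[b] = res.statistic, res.pvalue
    return BinComparison(labels=labels, ks_stat=ks, p_value=p,
                         n_real=nr, n_random=ns, real_mean=rm, random_mean=sm)


def ks_per_bin_permutation(real_means: np.ndarray, random_means: np.ndarray,
                           labels: list[str], n_perm: int = 1000,
                           seed: int = 0) -> BinComparison:
    """Permutation-based KS p-values (small-sample oracle for ks_per_bin)."""
    rng = np.random.default_rng(seed)
    n_bins = real_means.shape[1]
    ks = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    for b in range(n_bins):
        a = real_means[:, b]
        c = random_means[:, b]
        a, c = a[np.isfinite(a)], c[np.isfinite(c)]
        if len(a) < 2 or len(c) < 2:
            continue
        obs = sstats.ks_2samp(a, c).statistic
        pooled = np.concatenate([a, c])
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            d = sstats.ks_2samp(pooled[: len(a)], pooled[len(a):]).statistic
            count += d >= obs
        ks[b] = obs
        p[b] = (count + 1) / (n_perm + 1)
    return BinComparison(labels=labels, ks_stat=ks, p_value=p,
                         n_real=np.array([len(a)] * n_bins),
                         n_random=np.array([len(c)] * n_bins),
                         real_mean=np.full(n_bins, np.nan),
                         random_mean=np.full(n_bins, np.nan))


def write_results_csv(bin_tables: dict, path) -> None:
    """Write parameter-by-bin KS results (the Table-1-shaped grid) as CSV."""
    import pandas as pd

    rows = []
    for name, bc in bin_tables.items():
        for i, lab in enumerate(bc.labels):
            rows.append({
                "parameter": name, "bin": lab,
                "ks_stat": bc.ks_stat[i], "p_value": bc.p_value[i],
                "real_mean": bc.real_mean[i], "random_mean": bc.random_mean[i],
                "n_real": bc.n_real[i], "n_random": bc.n_random[i],
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_results_csv(path) -> dict:
    """Read a results CSV back into {parameter: BinComparison}."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"parameter", "bin", "ks_stat", "p_value", "real_mean",
                "random_mean", "n_real", "n_random"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = {}
    for name, g in df.groupby("parameter", sort=False):
        out[name] = BinComparison(
            labels=list(g["bin"]),
            ks_stat=g["ks_stat"].to_numpy(float),
            p_value=g["p_value"].to_numpy(float),
            n_real=g["n_real"].to_numpy(int),
            n_random=g["n_random"].to_numpy(int),
            real_mean=g["real_mean"].to_numpy(float),
            random_mean=g["random_mean"].to_numpy(float),
        )
    return out


# ---------------------------------------------------------------------------
# circular statistics


def circular_mean_R(angles_deg) -> tuple[float, float]:
    """Circular mean (deg) and resultant-vector strength R of angles."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    if len(a) == 0:
        raise ValueError("no valid angles")
    z = np.exp(1j * a).mean()
    return float(np.degrees(np.angle(z))), float(np.abs(z))


def circular_mean_R_rows(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column circular mean (deg) and R across rows, NaN-aware."""
    z = np.exp(1j * np.radians(rows))
    with np.errstate(invalid="ignore"):
        zm = np.nanmean(z, axis=0)
    return np.degrees(np.angle(zm)), np.abs(zm)


def _period_R(rows: np.ndarray, time_axis: np.ndarray,
              lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-row circular mean and R over time_axis in [lo, hi)."""
    sel = (time_axis >= lo) & (time_axis < hi)
    z = np.exp(1j * np.radians(rows[:, sel]))
    with np.errstate(invalid="ignore"):
        zm = np.nanmean(z, axis=1)
    return np.degrees(np.angle(zm)), np.abs(zm)


def angle_deviation_distributions(windows: PeriEventSet, config: AnalysisConfig,
                                  which: str = "real") -> tuple[np.ndarray, np.ndarray]:
    """Pooled wrapped deviations from each row's before/after circular mean.

    Per row: circular mean over [-angle_mean_window, 0) and [0,
    +angle_mean_window); deviations are (instantaneous - period mean)
    wrapped to (-180, 180], pooled across rows.  Rows with an all-invalid
    period are skipped.
    """
    rows = windows.real if which == "real" else windows.random
    w = config.angle_mean_window
    out = []
    for lo, hi in ((-w, 0.0), (0.0, w)):
        sel = (windows.time_axis >= lo) & (windows.time_axis < hi)
        mean_deg, _ = _period_R(rows, windows.time_axis, lo, hi)
        dev = wrap_deg(rows[:, sel] - mean_deg[:, None])
        keep = np.isfinite(mean_deg)
        out.append(dev[keep][np.isfinite(dev[keep])])
    return out[0], out[1]


@dataclass
class PairedRResult:
    r_before: np.ndarray
    r_after: np.ndarray
    statistic: float
    p_value: float
    n: int


def paired_R_test(windows: PeriEventSet, config: AnalysisConfig,
                  which: str = "real") -> PairedRResult:
    """Wilcoxon signed-rank on per-trajectory before/after R pairs.

    R is computed over the ``angle_mean_window`` periods on either side of
    t = 0.  Exact null distribution for n <= 25 pairs, normal approximation
    with continuity correction above.
    """
    rows = windows.real if which == "real" else windows.random
    w = config.angle_mean_window
    _, r_b = _period_R(rows, windows.time_axis, -w, 0.0)
    _, r_a = _period_R(rows, windows.time_axis, 0.0, w)
    keep = np.isfinite(r_b) & np.isfinite(r_a)
    r_b, r_a = r_b[keep], r_a[keep]
    n = len(r_b)
    if n < 6:
        raise ValueError(f"need at least 6 rows with both periods valid, got {n}")
    diffs = r_a - r_b
    if np.allclose(diffs, 0):
        return PairedRResult(r_b, r_a, np.nan, 1.0, n)
    res = sstats.wilcoxon(r_a, r_b, correction=True,
                          method="exact" if n <= 25 else "approx")
    return PairedRResult(r_b, r_a, float(res.statistic), float(res.pvalue), n)


# ---------------------------------------------------------------------------
# 0-degree crossing rates


def crossing_windows(crossings: np.ndarray, centers: np.ndarray,
                     window_half: float) -> list[np.ndarray]:
    """Onset-relative crossing times within [-window_half, window_half]."""
    out = []
    for c in np.asarray(centers, dtype=float):
        rel = np.asarray(crossings, dtype=float) - c
        out.append(rel[np.abs(rel) <= window_half])
    return out


def zscored_crossing_rate(crossings_per_row: list[np.ndarray],
                          config: AnalysisConfig,
                          dt: float = 1.0 / 30.0):
    """Mean +- SEM of per-row z-scored rolling 0-crossing rates.

    Per row, crossings are counted in a centered ``crossing_rate_window``
    rolling over the peri-event axis (only where the full window fits inside
    [-window_half, +window_half], avoiding edge artifacts; events/s), then
    z-scored against that row's own mean and SD.  Rows with zero crossings
    have no defined z-score and are excluded; the count of excluded rows is
    returned.

    Returns (time_axis, mean, sem, n_used, n_excluded, z_rows).
    """
    wh = config.window_half
    half = config.crossing_rate_window / 2.0
    axis = np.arange(-wh + half, wh - half + dt / 2, dt)
    lo = axis - half
    hi = axis + half
    width = np.full_like(axis, 2.0 * half)
    z_rows = []
    n_excluded = 0
    for cr in crossings_per_row:
        cr = np.asarray(cr, dtype=float)
        if len(cr) == 0:
            n_excluded += 1
            continue
        counts = np.searchsorted(np.sort(cr), hi, side="right") - \
            np.searchsorted(np.sort(cr), lo, side="left")
        rate = counts / width
        sd = rate.std()
        # an exactly constant rate has no scale; its z-curve is flat zero
        z_rows.append((rate - rate.mean()) / sd if sd > 0 else np.zeros_like(rate))
    if not z_rows:
        raise ValueError("no rows with a defined z-scored rate")
    Z = np.vstack(z_rows)
    return axis, Z.mean(axis=0), Z.std(axis=0, ddof=1) / np.sqrt(len(Z)), \
        len(Z), n_excluded, Z
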