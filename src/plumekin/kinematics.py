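"""Angle and speed kinematics from tracked nose/neck/body keypoints.

Sign conventions
----------------
Keypoints arrive in image coordinates (origin top-left, y down).  All signed
angles are computed via atan2 of planar cross/dot products in a mathematical
y-up frame (obtained by negating image y), then expressed in degrees wrapped
to (-180, 180].  Because an overhead camera renders the world faithfully,
"clockwise as seen on screen" equals clockwise in the y-up frame.

* body angle: let ``m`` be the neck-body midpoint, ``h`` the heading vector
  and ``p = port - m`` the vector to the odor source.  The angle is positive
  when ``h`` is clockwise of ``p`` on screen, and 0 when the animal is aimed
  at the port.  By default the heading is the forward vector ``m - body``;
  the literal backward reading (``body - m``, which scores a port-facing
  animal as 180 deg) is available via ``body_angle_forward=False``.
* head yaw: angle between the head vector ``nose - neck`` and the forward
  body axis ``neck - body``; an egocentric left head turn is positive, a
  right turn negative.

Frames in which any required keypoint is masked (pose likelihood below the
configured minimum) or degenerate (coincident keypoints) are invalid and
carry NaN angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import KeypointTrack, TimeSeries

__all__ = [
    "AngleSeries",
    "mask_low_likelihood",
    "body_angle",
    "head_yaw",
    "speed",
    "zero_crossings",
    "signed_angle_deg",
    "wrap_deg",
]


def wrap_deg(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    return -np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) + 180.0


def signed_angle_deg(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Signed angle (deg) from ``v_from`` to ``v_to`` in a y-up frame, CCW > 0.

    Vectors are given in image coordinates (y down); the y flip happens here.
    Degenerate (zero-length) vectors yield NaN.
    """
    v_from = np.asarray(v_from, dtype=float)
    v_to = np.asarray(v_to, dtype=float)
    # negating y flips the sign of the planar cross product only
    cross = -(v_from[..., 0] * v_to[..., 1] - v_from[..., 1] * v_to[..., 0])
    dot = v_from[..., 0] * v_to[..., 0] + v_from[..., 1] * v_to[..., 1]
    ang = np.degrees(np.arctan2(cross, dot))
    bad = (np.hypot(v_from[..., 0], v_from[..., 1]) == 0) | \
          (np.hypot(v_to[..., 0], v_to[..., 1]) == 0)
    return np.where(bad, np.nan, ang)


@dataclass
class AngleSeries:
    """A per-frame angle trace in degrees, wrapped to (-180, 180]."""

    t: np.ndarray
    angle: np.ndarray  # NaN on invalid frames
    valid: np.ndarray
    fps: float
    t0: float = 0.0

    def index_at(self, t) -> np.ndarray:
        idx = np.rint((np.asarray(t) - self.t0) * self.fps).astype(int)
        return np.clip(idx, 0, len(self.angle) - 1)


def mask_low_likelihood(track: KeypointTrack, likelihood_min: float) -> KeypointTrack:
    """Set coordinates of keypoints with likelihood < threshold to NaN."""
    out = track.copy()
    for part in ("nose", "neck", "body"):
        bad = getattr(out, f"{part}_p") < likelihood_min
        getattr(out, part)[bad] = np.nan
    return out


def body_angle(track: KeypointTrack, port_xy, forward: bool = True) -> AngleSeries:
    """Signed angle between the body heading and the direction to the port.

    Expects a likelihood-masked track (see :func:`mask_low_likelihood`);
    frames with a masked or degenerate neck/body pair are invalid.
    """
    port = np.asarray(port_xy, dtype=float)
    m = 0.5 * (track.neck + track.body)
    h = (m - track.body) if forward else (track.body - m)
    p = port - m
    # positive = heading clockwise of the port direction on screen
    ang = -signed_angle_deg(p, h)
    ang = wrap_deg(ang)
    valid = np.isfinite(ang)
    ang = np.where(valid, ang, np.nan)
    return AngleSeries(t=track.times, angle=ang, valid=valid, fps=track.fps, t0=track.t0)


def head_yaw(track: KeypointTrack) -> AngleSeries:
    """Signed head-yaw angle; egocentric left turn positive, right negative."""
    hv = track.nose - track.neck
    fv = track.neck - track.body  # 180-deg rotation of the body-neck vector
    ang = signed_angle_deg(fv, hv)  # left (screen-CCW) positive
    ang = wrap_deg(ang)
    valid = np.isfinite(ang)
    ang = np.where(valid, ang, np.nan)
    return AngleSeries(t=track.times, angle=ang, valid=valid, fps=track.fps, t0=track.t0)


def speed(track: KeypointTrack, smoothing_window: float = 0.5) -> TimeSeries:
    """Body-keypoint speed in px/s, boxcar-smoothed; masked frames give gaps."""
    disp = np.full(track.n, np.nan)
    d = np.hypot(*np.diff(track.body, axis=0).T) * track.fps
    disp[1:] = d
    w = max(1, int(round(smoothing_window * track.fps)))
    sm = pd.Series(disp).rolling(w, center=True, min_periods=1).mean().to_numpy()
    sm[np.isnan(disp)] = np.nan
    sm[0] = sm[1] if track.n > 1 else np.nan
    return TimeSeries(track.t0, track.fps, sm)


def zero_crossings(yaw: AngleSeries) -> np.ndarray:
    """Times (s) of 0-deg sign changes between consecutive valid frames.

    An exact 0 takes the sign of the following sample; crossings spanning an
    invalid gap are not counted.  Crossing times are linearly interpolated.
    """
    y = yaw.angle
    valid = yaw.valid
    s = np.sign(y)
    # exact zeros adopt the sign of the following sample (zeros are rare,
    # so a reverse scan over them is cheap)
    for i in np.flatnonzero(s == 0)[::-1]:
        s[i] = s[i + 1] if i + 1 < len(s) else 0.0
    pair_ok = valid[:-1] & valid[1:]
    crossing = pair_ok & (s[:-1] * s[1:] < 0)
    idx = np.flatnonzero(crossing)
    if len(idx) == 0:
        return np.array([])
    frac = y[idx] / (y[idx] - y[idx + 1])
    return yaw.t[idx] + frac / yaw.fps
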