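"""Withdrawal-response feature extraction from preprocessed paw tracks.

The response is segmented at t*, the frame of the paw's first local height
maximum, into a reflexive phase (rapid initial withdrawal, pre-t*) and an
affective phase (post-t* shaking and guarding).  Reflexive metrics are the
maximum paw height, maximum horizontal and vertical speeds, and path length
up to t*; affective metrics are shake count, shaking and guarding
durations, and post-t* path length.  Withdrawal latency is measured against
the stimulus trajectory: the first time after mesh crossing at which the
tracked point rises above the stimulus tip.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np

from .preprocess import PreprocessConfig, preprocess
from .stimulus import StimulusProfile, mesh_crossing_time, above_mesh_duration
from .track_io import Calibration, PoseTrack, apply_calibration

__all__ = [
    "FeatureConfig",
    "WithdrawalFeatures",
    "TStar",
    "paw_velocity",
    "find_t_star",
    "withdrawal_latency",
    "reflexive_features",
    "detect_shakes",
    "detect_guarding",
    "extract_features",
    "AlignmentError",
]

SHAKE_RUN_GAP_S = 0.05  # shakes closer than this merge into one bout


class AlignmentError(ValueError):
    """Track and stimulus clocks are inconsistent."""


@dataclass(frozen=True)
class FeatureConfig:
    """Detection thresholds for the affective-phase scorers.

    shake_height_mm : minimum paw height for an oscillation to count as
        shaking (default 0.35 mm).
    y_lift_mm : height defining a paw lift / response onset (default 0.5 mm).
    guard_height_mm : sustained elevation threshold for guarding; tied to
        the paw-lift threshold by default.
    shake_speed_mm_s : minimum peak vertical speed on both sides of a
        velocity inflection for it to count as a shake (default 50 mm/s) —
        quantifies "rapid".
    behavior_window_s : post-stimulus window for the windowed travel
        distance (default 1.5 s from mesh crossing).
    node : tracked point the features are computed on.
    path_2d : if False, distances use vertical motion only.
    """

    shake_height_mm: float = 0.35
    y_lift_mm: float = 0.5
    guard_height_mm: float = 0.5
    shake_speed_mm_s: float = 50.0
    behavior_window_s: float = 1.5
    node: str = "center"
    shake_axis: str = "y"
    path_2d: bool = True

    def __post_init__(self) -> None:
        for name in ("shake_height_mm", "y_lift_mm", "guard_height_mm",
                     "shake_speed_mm_s", "behavior_window_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class WithdrawalFeatures:
    """Per-trial feature record (the batch CSV row)."""

    trial_id: str = ""
    t_star_s: float = np.nan
    latency_s: float | None = None
    max_height_mm: float = 0.0
    max_x_velocity_mm_s: float = 0.0
    max_y_velocity_mm_s: float = 0.0
    distance_reflexive_mm: float = 0.0
    distance_affective_mm: float = 0.0
    n_shakes: int = 0
    shaking_duration_s: float = 0.0
    guarding_duration_s: float = 0.0
    distance_windowed_mm: float = 0.0
    responded: bool = False
    pre_lifted: bool = False
    no_descent: bool = False

    def to_row(self) -> dict:
        row = asdict(self)
        row["latency_s"] = np.nan if self.latency_s is None else self.latency_s
        return row


class TStar(NamedTuple):
    index: int
    no_descent: bool


def paw_velocity(track: PoseTrack, node: str = "center") -> np.ndarray:
    """Per-frame 2D velocity (mm/s): central differences, one-sided edges."""
    if track.units != "mm":
        raise ValueError("velocity requires a calibrated (mm) track")
    xy = track.node_xy(node)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    return np.gradient(xy, 1.0 / track.fps, axis=0)


def find_t_star(heights: np.ndarray, y_lift_mm: float = 0.5) -> TStar:
    """Frame of the first local height maximum of the withdrawal rise.

    Only the rise above the paw-lift threshold is considered; plateaus
    resolve to their last frame.  A monotone non-decreasing series returns
    the last index flagged ``no_descent``.
    """
    h = np.asarray(heights, dtype=float)
    above = np.nonzero(h > y_lift_mm)[0]
    if above.size == 0:
        raise ValueError("no response: series never exceeds the paw-lift threshold")
    onset = int(above[0])
    n = len(h)
    for i in range(max(onset, 1), n - 1):
        if h[i] >= h[i - 1] and h[i] > h[i + 1]:
            return TStar(i, False)
    return TStar(n - 1, True)


def withdrawal_latency(track: PoseTrack, profile: StimulusProfile,
                       node: str = "center", y_lift_mm: float = 0.5,
                       ) -> tuple[float | None, bool]:
    """Latency from stimulus–paw contact to paw overtaking the stimulus.

    The track must be time-aligned so t=0 is stimulus motion onset.  While
    the stimulus is above the mesh, latency is the first time the paw
    height exceeds the stimulus tip height above the mesh, minus the
    mesh-crossing time.  If the paw only rises above the paw-lift threshold
    after the stimulus retracts, that lift time is used.  Returns
    ``(latency, pre_lifted)``; latency is None for a non-response.
    """
    tc = mesh_crossing_time(profile)
    if tc is None:
        raise AlignmentError("stimulus never crosses the mesh; latency undefined")
    t = track.times
    if t[-1] < tc:
        raise AlignmentError("track ends before the stimulus crosses the mesh")
    h = track.node_xy(node)[:, 1]
    stim_up = tc + above_mesh_duration(profile)
    during = (t >= tc) & (t <= stim_up)
    stim_above_mesh = profile.height(t[during]) - profile.mesh_offset_mm
    # the paw must also clear the lift threshold: at the crossing instant the
    # trajectory sits exactly at mesh level and bare tracking noise would
    # otherwise register a zero-latency "withdrawal"
    margin = h[during] - np.maximum(stim_above_mesh, y_lift_mm)
    over = margin > 0
    td = t[during]
    if over.any():
        k = int(np.argmax(over))
        t_hit = _subframe_crossing(td, margin, k)
        return float(t_hit - tc), k == 0
    after = t > stim_up
    if after.any():
        ta = t[after]
        margin_a = h[after] - y_lift_mm
        lifted = margin_a > 0
        if lifted.any():
            k = int(np.argmax(lifted))
            return float(_subframe_crossing(ta, margin_a, k) - tc), False
    return None, False


def _subframe_crossing(t: np.ndarray, margin: np.ndarray, k: int) -> float:
    """Linear sub-frame estimate of where ``margin`` first crosses zero."""
    if k == 0 or margin[k - 1] > 0 or margin[k] == margin[k - 1]:
        return float(t[k])
    frac = -margin[k - 1] / (margin[k] - margin[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def _path_length(xy: np.ndarray, path_2d: bool) -> float:
    if xy.shape[0] < 2:
        return 0.0
    steps = np.diff(xy, axis=0)
    if not path_2d:
        return float(np.abs(steps[:, 1]).sum())
    return float(np.linalg.norm(steps, axis=1).sum())


def reflexive_features(track: PoseTrack, t_star: int, node: str = "center",
                       y_lift_mm: float = 0.5, path_2d: bool = True) -> dict:
    """Max height, max |vx|, max |vy| and path length from response onset to t*."""
    h = track.node_xy(node)[:, 1]
    above = np.nonzero(h > y_lift_mm)[0]
    onset = int(above[0]) if above.size else 0
    # walk back to the start of the monotone rise so the path length covers
    # the full lift, not just the part above the threshold
    while onset > 0 and h[onset - 1] < h[onset]:
        onset -= 1
    onset = min(onset, t_star)
    vel = paw_velocity(track, node)
    seg = slice(onset, t_star + 1)
    return {
        "max_height_mm": float(h[seg].max()),
        "max_x_velocity_mm_s": float(np.abs(vel[seg, 0]).max()),
        "max_y_velocity_mm_s": float(np.abs(vel[seg, 1]).max()),
        "distance_reflexive_mm": _path_length(track.node_xy(node)[seg], path_2d),
    }


def _smooth5(v: np.ndarray) -> np.ndarray:
    # 5-sample moving average suppressing single-frame noise inflections
    if len(v) < 5:
        return v.copy()
    kernel = np.ones(5) / 5.0
    out = np.convolve(v, kernel, mode="same")
    out[:2] = v[:2]
    out[-2:] = v[-2:]
    return out


def detect_shakes(track: PoseTrack, t_star: int,
                  cfg: FeatureConfig | None = None) -> tuple[np.ndarray, float]:
    """Shake events in the affective phase.

    A shake is a sign change of the smoothed vertical velocity while the
    paw is at or above the shaking height threshold, with peak speed at or
    above ``shake_speed_mm_s`` on both sides of the inflection.  Shakes
    separated by less than 50 ms merge into bouts; shaking duration is the
    total time spanned by those bouts.
    """
    cfg = cfg or FeatureConfig()
    h = track.node_xy(cfg.node)[:, 1]
    axis = 1 if cfg.shake_axis == "y" else 0
    # differentiate within the affective segment only: a one-sided difference
    # at t* keeps the pre-t* rise from injecting a spurious inflection at the
    # withdrawal peak itself
    seg = track.node_xy(cfg.node)[t_star:, axis]
    if len(seg) < 3:
        return np.asarray([]), 0.0
    v = _smooth5(np.gradient(seg, 1.0 / track.fps))
    hh = h[t_star:]
    t = track.times[t_star:]
    sign = np.sign(v)
    nz = sign != 0
    # treat exact zeros as continuation of the previous sign
    running = sign.copy()
    for i in range(1, len(running)):
        if running[i] == 0:
            running[i] = running[i - 1]
    changes = np.nonzero(running[1:] * running[:-1] < 0)[0] + 1
    shake_times = []
    bounds = np.concatenate(([0], changes, [len(v)]))
    for j, idx in enumerate(changes):
        if hh[idx] < cfg.shake_height_mm:
            continue
        left = np.abs(v[bounds[j]:idx + 1]).max(initial=0.0)
        right = np.abs(v[idx:bounds[j + 2]]).max(initial=0.0)
        if left >= cfg.shake_speed_mm_s and right >= cfg.shake_speed_mm_s:
            shake_times.append(t[idx])
    shake_times = np.asarray(shake_times)
    duration = 0.0
    if shake_times.size > 1:
        gaps = np.diff(shake_times)
        run_start = shake_times[0]
        prev = shake_times[0]
        for st, gap in zip(shake_times[1:], gaps):
            if gap >= SHAKE_RUN_GAP_S:
                duration += prev - run_start
                run_start = st
            prev = st
        duration += prev - run_start
    return shake_times, float(duration)


def shake_intervals(shake_times: np.ndarray) -> list[tuple[float, float]]:
    """Maximal bouts of shakes separated by less than 50 ms."""
    if shake_times.size == 0:
        return []
    out = []
    start = prev = shake_times[0]
    for st in shake_times[1:]:
        if st - prev >= SHAKE_RUN_GAP_S:
            out.append((float(start), float(prev)))
            start = st
        prev = st
    out.append((float(start), float(prev)))
    return out


def detect_guarding(track: PoseTrack, t_star: int,
                    cfg: FeatureConfig | None = None,
                    shakes: np.ndarray | None = None,
                    ) -> tuple[list[tuple[float, float]], float]:
    """Guarding: sustained post-t* elevation that is not shaking.

    Maximal intervals with height at or above ``guard_height_mm`` are
    found, shake-bout intervals are subtracted, and the total remaining
    length is the guarding duration.
    """
    cfg = cfg or FeatureConfig()
    if shakes is None:
        shakes, _ = detect_shakes(track, t_star, cfg)
    h = track.node_xy(cfg.node)[t_star:, 1]
    t = track.times[t_star:]
    up = h >= cfg.guard_height_mm
    intervals = []
    i = 0
    n = len(up)
    while i < n:
        if up[i]:
            j = i
            while j + 1 < n and up[j + 1]:
                j += 1
            intervals.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    bouts = shake_intervals(np.asarray(shakes))
    guard = []
    for lo, hi in intervals:
        segs = [(lo, hi)]
        for blo, bhi in bouts:
            next_segs = []
            for slo, shi in segs:
                if bhi <= slo or blo >= shi:
                    next_segs.append((slo, shi))
                    continue
                if slo < blo:
                    next_segs.append((slo, blo))
                if bhi < shi:
                    next_segs.append((bhi, shi))
            segs = next_segs
        guard.extend(segs)
    duration = float(sum(hi - lo for lo, hi in guard))
    return guard, duration


def extract_features(track: PoseTrack, profile: StimulusProfile,
                     pre_cfg: PreprocessConfig | None = None,
                     feat_cfg: FeatureConfig | None = None,
                     calibration: Calibration | None = None,
                     trial_id: str = "") -> WithdrawalFeatures:
    """Run the full chain on a raw track and return one feature record.

    Stages: (calibrate if needed) → preprocess → t* → latency → reflexive →
    affective → windowed distance.  Deterministic for identical input.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    if track.units == "px":
        if calibration is None:
            raise ValueError("pixel-space track requires a calibration")
        track = apply_calibration(track, calibration)
    if "baseline" not in track.meta.get("stages", []):
        track = preprocess(track, pre_cfg, stim_onset_s=0.0)

    out = WithdrawalFeatures(trial_id=trial_id)
    tc = mesh_crossing_time(profile)
    if tc is None:
        raise AlignmentError("stimulus profile never crosses the mesh")
    h = track.node_xy(feat_cfg.node)[:, 1]
    t = track.times

    latency, pre_lifted = withdrawal_latency(track, profile, feat_cfg.node,
                                             feat_cfg.y_lift_mm)
    out.latency_s = latency
    out.pre_lifted = pre_lifted
    out.responded = (h > feat_cfg.y_lift_mm).any()
    if not out.responded:
        return out

    ts = find_t_star(h, feat_cfg.y_lift_mm)
    out.no_descent = ts.no_descent
    out.t_star_s = float(t[ts.index])
    out.__dict__.update(reflexive_features(track, ts.index, feat_cfg.node,
                                           feat_cfg.y_lift_mm, feat_cfg.path_2d))
    shakes, shake_dur = detect_shakes(track, ts.index, feat_cfg)
    out.n_shakes = int(len(shakes))
    out.shaking_duration_s = shake_dur
    _, guard_dur = detect_guarding(track, ts.index, feat_cfg, shakes=shakes)
    out.guarding_duration_s = guard_dur
    out.distance_affective_mm = _path_length(
        track.node_xy(feat_cfg.node)[ts.index:], feat_cfg.path_2d)
    win = (t >= tc) & (t <= tc + feat_cfg.behavior_window_s)
    out.distance_windowed_mm = _path_length(
        track.node_xy(feat_cfg.node)[win], feat_cfg.path_2d)
    return out
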