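"""Pose-track preprocessing: confidence gating, smoothing, resizing, baselining.

The canonical order, enforced by :func:`preprocess`, is
calibrate → interpolate → resize → filter → baseline.  Each stage returns a
new track and records itself in ``track.meta["stages"]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .track_io import PoseTrack, StateError

__all__ = [
    "PreprocessConfig",
    "interpolate_low_confidence",
    "rolling_mean_filter",
    "resize_to_reference_rate",
    "baseline_reference",
    "preprocess",
    "UnrecoverableTrackError",
]


class UnrecoverableTrackError(ValueError):
    """A node has no confidently tracked samples at all."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults match the reference analysis settings.

    p_cutoff : tracking-confidence threshold below which samples are
        replaced by linear interpolation (default 0.45).
    window : rolling mean filter length in frames (default 17, odd).
    reference_fps : common timeline all videos are standardized to
        (default 2000 fps).
    baseline_height_mm : fixed height band above rest treated as "at rest"
        by downstream detectors (default 1.0 mm).
    """

    p_cutoff: float = 0.45
    window: int = 17
    reference_fps: float = 2000.0
    baseline_height_mm: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cutoff <= 1.0:
            raise ValueError("p_cutoff must be in [0, 1]")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if not self.reference_fps > 0:
            raise ValueError("reference_fps must be positive")


def interpolate_low_confidence(track: PoseTrack, p_cutoff: float = 0.45) -> PoseTrack:
    """Replace low-confidence or missing samples with linear interpolation.

    Samples with confidence below ``p_cutoff`` (or NaN coordinates) are
    rebuilt by linear interpolation between the nearest flanking samples at
    or above the cutoff; leading/trailing runs are filled from the nearest
    valid sample rather than extrapolated.  Samples at or above the cutoff
    are left bit-identical.  The per-node boolean mask of replaced samples
    is stored in ``meta["interpolated"]``.
    """
    out = track.copy()
    n = track.n_frames
    idx = np.arange(n)
    flagged = np.zeros((len(track.node_names), n), dtype=bool)
    for i in range(len(track.node_names)):
        conf = track.confidence[i]
        finite = np.all(np.isfinite(track.coords[i]), axis=1)
        valid = (conf >= p_cutoff) & finite
        if not valid.any():
            raise UnrecoverableTrackError(
                f"node {track.node_names[i]!r}: no samples at confidence >= {p_cutoff}")
        bad = ~valid
        flagged[i] = bad
        if bad.any():
            for ax in range(2):
                series = out.coords[i, :, ax]
                series[bad] = np.interp(idx[bad], idx[valid],
                                        track.coords[i, valid, ax])
    out.meta["interpolated"] = flagged
    out.meta.setdefault("stages", []).append("interpolate")
    return out


def _centered_mean(series: np.ndarray, window: int) -> np.ndarray:
    # shrinking centered window: output[i] = mean(series[i-h : i+h+1] clipped)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(series)))
    n = len(series)
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def rolling_mean_filter(track: PoseTrack, window: int = 17) -> PoseTrack:
    """Centered moving-average filter; edges use shrinking windows."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > track.n_frames:
        raise ValueError(f"window {window} exceeds frame count {track.n_frames}")
    out = track.copy()
    for i in range(len(track.node_names)):
        for ax in range(2):
            out.coords[i, :, ax] = _centered_mean(track.coords[i, :, ax], window)
    out.meta.setdefault("stages", []).append("filter")
    return out


def resize_to_reference_rate(track: PoseTrack, reference_fps: float = 2000.0) -> PoseTrack:
    """Re-express a track on the reference-rate timeline.

    Below the reference rate the sample count is multiplied by
    ``reference_fps / fps`` with linear interpolation between original
    samples (original samples land exactly on the new grid when the ratio is
    an integer); above it, the track is downsampled.  The total covered
    duration ``n / fps`` is preserved.  At the reference rate this is the
    identity.
    """
    if not reference_fps > 0:
        raise ValueError("reference_fps must be positive")
    if track.fps == reference_fps:
        return track.copy()
    n = track.n_frames
    n_out = int(round(n * reference_fps / track.fps))
    t_in = np.arange(n) / track.fps
    t_out = np.arange(n_out) / reference_fps
    out = track.copy()
    coords = np.empty((len(track.node_names), n_out, 2))
    conf = np.empty((len(track.node_names), n_out))
    for i in range(len(track.node_names)):
        for ax in range(2):
            coords[i, :, ax] = np.interp(t_out, t_in, track.coords[i, :, ax])
        conf[i] = np.clip(np.interp(t_out, t_in, track.confidence[i]), 0.0, 1.0)
    out.coords = coords
    out.confidence = conf
    out.fps = reference_fps
    out.meta.setdefault("stages", []).append("resize")
    return out


def baseline_reference(track: PoseTrack, baseline_height_mm: float = 1.0,
                       stim_onset_s: float = 0.0, bin_mm: float = 0.1) -> PoseTrack:
    """Re-express vertical coordinates as height above the resting paw.

    The rest level of each node is the modal pre-stimulus vertical value,
    binned at ``bin_mm`` — the mode is robust to transient tracking
    undershoot, unlike the minimum.  With no usable pre-stimulus frames the
    mode is taken over the whole track and a warning is issued.
    ``baseline_height_mm`` travels with the track for downstream detectors.
    """
    if track.units != "mm":
        raise StateError("baseline referencing requires a calibrated (mm) track")
    out = track.copy()
    pre = track.times < stim_onset_s
    rests = []
    for i in range(len(track.node_names)):
        y = track.coords[i, :, 1]
        y_pre = y[pre & np.isfinite(y)]
        if y_pre.size == 0:
            warnings.warn(
                f"node {track.node_names[i]!r}: no pre-stimulus frames; "
                "using global modal rest level", stacklevel=2)
            y_pre = y[np.isfinite(y)]
        rest = _modal_value(y_pre, bin_mm)
        out.coords[i, :, 1] = y - rest
        rests.append(rest)
    out.meta["rest_level_mm"] = np.array(rests)
    out.meta["baseline_height_mm"] = baseline_height_mm
    out.meta.setdefault("stages", []).append("baseline")
    return out


def _modal_value(values: np.ndarray, bin_width: float) -> float:
    if values.size == 0:
        raise ValueError("cannot take the mode of an empty series")
    lo = values.min()
    nbins = max(1, int(np.ceil((values.max() - lo) / bin_width)) + 1)
    counts, edges = np.histogram(values, bins=nbins,
                                 range=(lo - bin_width / 2, lo - bin_width / 2 + nbins * bin_width))
    k = int(np.argmax(counts))
    in_bin = values[(values >= edges[k]) & (values < edges[k + 1])]
    # center of mass of the modal bin, not the bin edge
    return float(in_bin.mean()) if in_bin.size else float((edges[k] + edges[k + 1]) / 2)


def preprocess(track: PoseTrack, config: PreprocessConfig | None = None,
               stim_onset_s: float = 0.0) -> PoseTrack:
    """Run interpolate → resize → filter → baseline on a calibrated track.

    Resizing precedes the rolling filter so the filter window spans a fixed
    real-time extent (window / reference_fps seconds) regardless of the
    camera rate — a 500 fps video is smoothed identically to a 2000 fps one.
    """
    cfg = config or PreprocessConfig()
    if track.units != "mm":
        raise StateError("preprocess expects a calibrated (mm) track; "
                         "apply_calibration first")
    t = interpolate_low_confidence(track, cfg.p_cutoff)
    t = resize_to_reference_rate(t, cfg.reference_fps)
    t = rolling_mean_filter(t, min(cfg.window, t.n_frames - (1 - t.n_frames % 2)))
    t = baseline_reference(t, cfg.baseline_height_mm, stim_onset_s=stim_onset_s)
    return t
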