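"""Seeded synthetic-data generators with analytic ground truth.

Every input the pipeline consumes can be generated here: paw-withdrawal
pose tracks (configurable latency, peak height, shake oscillations,
guarding plateaus, tracking noise and dropout), compliant-paw force plants
for the closed-loop controller, and event-locked calcium recordings with
stated effect sizes.  Generators are deterministic under a fixed seed and
attach ground-truth records sufficient to score every extractor.

The withdrawal waveform family (half-cosine rise and descent, constant-
frequency shake bout, guarding plateau) is chosen for analytic
invertibility, not biomechanical realism.  Ground-truth feature values are
computed on the noiseless waveform passed through a continuous-time moving
average matching the default rolling-filter span, because the feature
definitions operate on the filtered track; the computation is a dense-grid
brute force independent of the extractor code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .perievent import CalciumRecording
from .stimulus import StimulusProfile, mesh_crossing_time, above_mesh_duration
from .track_io import PoseTrack

__all__ = [
    "WithdrawalParams",
    "CalciumSimParams",
    "synth_withdrawal_track",
    "synth_force_plant",
    "synth_calcium",
    "write_calcium_csv",
    "read_calcium_csv",
    "write_calcium_hdf5",
    "read_calcium_hdf5",
]

# detector defaults the ground truth is scored against
_FILTER_SPAN_S = 17 / 2000.0
_GUARD_THRESHOLD_MM = 0.5
_Y_LIFT_MM = 0.5


@dataclass(frozen=True)
class WithdrawalParams:
    """Programmed shape of one synthetic withdrawal response.

    ``latency_s`` is the delay from mesh crossing to the start of the paw
    lift (None for a non-responder).  The paw rises by half-cosine to
    ``peak_height_mm`` over ``rise_time_s``, descends to the top of the
    shake band, oscillates at ``shake_freq_hz`` for exactly ``n_shakes``
    velocity inflections, holds a guarding plateau at ``guard_height_mm``
    for ``guard_duration_s`` and returns to rest.  Gaussian tracking noise
    (``noise_sd_mm``) and seeded low-confidence dropout frames exercise the
    interpolation gate.
    """

    latency_s: float | None = 0.06
    peak_height_mm: float = 5.0
    rise_time_s: float = 0.03
    n_shakes: int = 6
    shake_freq_hz: float = 20.0
    shake_amp_mm: float = 1.5
    guard_duration_s: float = 0.8
    guard_height_mm: float = 2.0
    noise_sd_mm: float = 0.02
    dropout_prob: float = 0.02
    fps: float = 2000.0
    seed: int = 0
    descend_time_s: float = 0.05
    return_time_s: float = 0.15
    pre_stim_s: float = 0.1
    scale_mm_per_px: float = 0.5
    known_mm: float = 50.0
    rest_y_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.latency_s is not None and self.latency_s < 0:
            raise ValueError("latency_s must be non-negative")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.fps <= 0 or self.peak_height_mm < 0 or self.noise_sd_mm < 0:
            raise ValueError("invalid withdrawal parameters")
        if (self.latency_s is not None and self.n_shakes > 0
                and self.peak_height_mm < self.guard_height_mm + self.shake_amp_mm):
            raise ValueError(
                "peak_height_mm must be >= guard_height_mm + shake_amp_mm: "
                "otherwise the programmed peak is not the first height maximum")


def _half_cos(s: np.ndarray) -> np.ndarray:
    # smooth 0→1 ramp on s in [0, 1]
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0.0, 1.0)))


def _withdrawal_waveform(p: WithdrawalParams, t_lift: float) -> Callable:
    """Noiseless paw height above rest as a vectorized function of time."""
    shake_top = p.guard_height_mm + p.shake_amp_mm
    bout_s = (p.n_shakes + 0.5) / (2.0 * p.shake_freq_hz) if p.n_shakes else 0.0
    t_peak = t_lift + p.rise_time_s
    t_bout = t_peak + p.descend_time_s
    t_guard = t_bout + bout_s
    t_return = t_guard + p.guard_duration_s
    t_end = t_return + p.return_time_s

    def height(t):
        t = np.asarray(t, dtype=float)
        h = np.zeros_like(t)
        m = (t >= t_lift) & (t < t_peak)
        h[m] = p.peak_height_mm * _half_cos((t[m] - t_lift) / p.rise_time_s)
        m = (t >= t_peak) & (t < t_bout)
        h[m] = p.peak_height_mm - (p.peak_height_mm - shake_top) * _half_cos(
            (t[m] - t_peak) / p.descend_time_s)
        if p.n_shakes:
            m = (t >= t_bout) & (t < t_guard)
            h[m] = p.guard_height_mm + p.shake_amp_mm * np.cos(
                2.0 * np.pi * p.shake_freq_hz * (t[m] - t_bout))
        m = (t >= t_guard) & (t < t_return)
        h[m] = p.guard_height_mm
        m = (t >= t_return) & (t < t_end)
        h[m] = p.guard_height_mm * (1.0 - _half_cos((t[m] - t_return) / p.return_time_s))
        return h

    height.t_lift = t_lift
    height.t_peak = t_peak
    height.t_bout = t_bout
    height.t_guard = t_guard
    height.t_end = t_end
    height.bout_s = bout_s
    return height


def _filtered(fn: Callable, t: np.ndarray, span: float = _FILTER_SPAN_S,
              k: int = 17) -> np.ndarray:
    # continuous-time centered moving average by midpoint quadrature
    offs = (np.arange(k) - (k - 1) / 2) / k * span
    return np.mean([fn(t + o) for o in offs], axis=0)


def _ground_truth(p: WithdrawalParams, profile: StimulusProfile,
                  wave: Callable, tc: float) -> dict:
    """Score the ideal noiseless measurement on a dense grid (0.05 ms)."""
    dt = 5e-5
    t = np.arange(0.0, wave.t_end + 0.2, dt)
    h = _filtered(wave, t)
    stim_up = tc + above_mesh_duration(profile)
    during = (t >= tc) & (t <= stim_up)
    stim_above = profile.height(t[during]) - profile.mesh_offset_mm
    over = (h[during] > stim_above) & (h[during] > _Y_LIFT_MM)
    if over.any():
        latency = float(t[during][np.argmax(over)] - tc)
    else:
        lifted = (t > stim_up) & (h > _Y_LIFT_MM)
        latency = float(t[lifted][0] - tc) if lifted.any() else None
    # first local maximum of the filtered waveform = argmax near the peak
    t_star = float(t[np.argmax(h)])
    peak = float(h.max())
    shake_times = (wave.t_bout
                   + np.arange(1, p.n_shakes + 1) / (2.0 * p.shake_freq_hz))
    # guarding: post-t* elevation >= threshold minus the shake-bout span
    post = t >= t_star
    up_int = []
    idx = np.nonzero(h[post] >= _GUARD_THRESHOLD_MM)[0]
    tp = t[post]
    if idx.size:
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        up_int = [(tp[idx[a]], tp[idx[b]]) for a, b in zip(starts, ends)]
    guard = 0.0
    bout_lo = shake_times[0] if p.n_shakes else None
    bout_hi = shake_times[-1] if p.n_shakes else None
    for lo, hi in up_int:
        length = hi - lo
        if p.n_shakes:
            overlap = max(0.0, min(hi, bout_hi) - max(lo, bout_lo))
            length -= overlap
        guard += length
    return {
        "latency_s": latency,
        "t_star_s": t_star,
        "peak_height_mm": peak,
        "n_shakes": int(p.n_shakes),
        "shake_times_s": shake_times.tolist(),
        "guard_duration_s": float(guard),
        "lift_time_s": float(wave.t_lift),
        "mesh_crossing_s": float(tc),
        "responded": True,
    }


def synth_withdrawal_track(p: WithdrawalParams, profile: StimulusProfile,
                           ) -> tuple[PoseTrack, dict]:
    """Generate one pixel-space withdrawal track plus its ground truth.

    The track starts ``pre_stim_s`` before stimulus motion onset (t=0),
    contains nodes heel/center/toe sharing the programmed vertical
    waveform, and reference nodes objectA/objectB separated by
    ``known_mm / scale_mm_per_px`` pixels so calibration recovers the true
    scale exactly.  Deterministic per seed.
    """
    tc = mesh_crossing_time(profile)
    if tc is None:
        raise ValueError("stimulus profile never crosses the mesh")
    rng = np.random.default_rng(p.seed)
    responder = p.latency_s is not None
    t_lift = tc + (p.latency_s if responder else 0.0)
    wave = _withdrawal_waveform(p, t_lift) if responder else None
    t_end = (wave.t_end if responder else tc + 1.0) + 0.2
    duration = p.pre_stim_s + t_end
    n = int(round(duration * p.fps))
    times = -p.pre_stim_s + np.arange(n) / p.fps

    y_rel = wave(times) if responder else np.zeros(n)
    if responder:
        truth = _ground_truth(p, profile, wave, tc)
    else:
        truth = {"latency_s": None, "t_star_s": None, "peak_height_mm": 0.0,
                 "n_shakes": 0, "shake_times_s": [], "guard_duration_s": 0.0,
                 "lift_time_s": None, "mesh_crossing_s": float(tc),
                 "responded": False}
    truth.update({"seed": p.seed, "fps": p.fps,
                  "scale_mm_per_px": p.scale_mm_per_px,
                  "known_mm": p.known_mm, "params": _params_dict(p)})

    node_names = ["heel", "center", "toe", "objectA", "objectB"]
    x_offsets = {"heel": -3.0, "center": 0.0, "toe": 3.0}
    coords = np.zeros((5, n, 2))
    confidence = np.zeros((5, n))
    for i, name in enumerate(node_names[:3]):
        x = 20.0 + x_offsets[name] + rng.normal(0.0, p.noise_sd_mm, n)
        y = p.rest_y_mm + y_rel + rng.normal(0.0, p.noise_sd_mm, n)
        coords[i, :, 0] = x
        coords[i, :, 1] = y
        confidence[i] = rng.uniform(0.8, 1.0, n)
        drop = rng.random(n) < p.dropout_prob
        coords[i, drop] = np.nan
        confidence[i, drop] = rng.uniform(0.0, 0.45, drop.sum())
    # chamber reference pair: fixed, separated by known_mm along x
    ref_sep_px = p.known_mm / p.scale_mm_per_px
    coords[3, :, 0], coords[3, :, 1] = 2.0 / p.scale_mm_per_px, 1.0 / p.scale_mm_per_px
    coords[4, :, 0] = 2.0 / p.scale_mm_per_px + ref_sep_px
    coords[4, :, 1] = 1.0 / p.scale_mm_per_px
    confidence[3] = confidence[4] = 1.0
    # paw nodes to pixel units
    coords[:3] /= p.scale_mm_per_px

    track = PoseTrack(node_names, coords, confidence, fps=p.fps, units="px",
                      meta={"t0_s": -p.pre_stim_s})
    return track, truth


def _params_dict(p: WithdrawalParams) -> dict:
    d = asdict(p)
    return d


# ---------------------------------------------------------------------------
# force plants

def synth_force_plant(kind: str, stiffness_g_per_mm: float = 2.0,
                      withdrawal_time_s: float | None = None) -> Callable:
    """Paw stand-ins for the closed-loop force controller.

    ``rigid`` senses exactly the commanded force (an unyielding contact);
    ``compliant`` is Hookean, force = stiffness × indentation;
    ``withdrawing`` is compliant until ``withdrawal_time_s`` and then reads
    zero within one control step (the paw is gone).
    """
    if kind == "rigid":
        def plant(t, commanded_g, z_mm):
            return commanded_g
    elif kind == "compliant":
        if stiffness_g_per_mm <= 0:
            raise ValueError("stiffness must be positive")

        def plant(t, commanded_g, z_mm):
            return stiffness_g_per_mm * z_mm
    elif kind == "withdrawing":
        if withdrawal_time_s is None or withdrawal_time_s <= 0:
            raise ValueError("withdrawing plant needs withdrawal_time_s > 0")

        def plant(t, commanded_g, z_mm):
            if t >= withdrawal_time_s:
                return 0.0
            return stiffness_g_per_mm * z_mm
    else:
        raise ValueError(f"unknown plant kind {kind!r}")
    plant.kind = kind
    return plant


# ---------------------------------------------------------------------------
# calcium

@dataclass(frozen=True)
class CalciumSimParams:
    """Event-locked calcium simulation.

    Defaults follow the recording conditions the analysis is designed for:
    20 Hz sampling, 10 stimulus events spaced 2 min apart after a baseline
    period.  Up-regulated cells add an exponentially decaying positive
    transient of amplitude ``transient_amp_sd_units × noise_sd`` after each
    event; down-regulated cells a matching negative deflection.
    """

    n_cells: int = 100
    frac_up: float = 0.15
    frac_down: float = 0.15
    transient_amp_sd_units: float = 3.0
    decay_s: float = 1.0
    noise_sd: float = 0.1
    n_events: int = 10
    fps: float = 20.0
    seed: int = 0
    inter_event_s: float = 120.0
    baseline_s: float = 30.0
    ar1_rho: float = 0.0
    event_label: str = "pinprick"

    def __post_init__(self) -> None:
        if not 0 <= self.frac_up + self.frac_down <= 1:
            raise ValueError("frac_up + frac_down must be in [0, 1]")
        if self.n_cells < 1 or self.n_events < 0 or self.fps <= 0:
            raise ValueError("invalid calcium simulation parameters")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")


def synth_calcium(p: CalciumSimParams,
                  behavior_values: np.ndarray | None = None,
                  behavior_coupling: float = 0.0,
                  session_id: str = "sim",
                  ) -> tuple[CalciumRecording, dict]:
    """Simulate ΔF/F traces with known up/down regulated cells.

    With ``behavior_coupling`` > 0 and per-event ``behavior_values`` b_e,
    the transient amplitude on event e is scaled by
    ``1 + coupling · (b_e − mean b) / std b``, giving the per-event
    regulation fractions a recoverable linear relation with behavior.
    """
    rng = np.random.default_rng(p.seed)
    n_up = int(round(p.frac_up * p.n_cells))
    n_down = int(round(p.frac_down * p.n_cells))
    if n_up + n_down > p.n_cells:
        raise ValueError("infeasible regulated-cell fractions")
    event_times = p.baseline_s + np.arange(p.n_events) * p.inter_event_s
    duration = p.baseline_s + p.n_events * p.inter_event_s + 10.0
    n_samples = int(round(duration * p.fps))
    t = np.arange(n_samples) / p.fps

    noise = rng.normal(0.0, p.noise_sd, (p.n_cells, n_samples))
    if p.ar1_rho > 0:
        for j in range(1, n_samples):
            noise[:, j] += p.ar1_rho * noise[:, j - 1]
        noise *= np.sqrt(1.0 - p.ar1_rho ** 2)
    traces = noise

    scales = np.ones(p.n_events)
    if behavior_values is not None and behavior_coupling != 0.0:
        b = np.asarray(behavior_values, dtype=float)
        if b.shape != (p.n_events,):
            raise ValueError("behavior_values must have one entry per event")
        sd = b.std()
        if sd > 0:
            scales = np.clip(1.0 + behavior_coupling * (b - b.mean()) / sd,
                             0.0, None)
    amp = p.transient_amp_sd_units * p.noise_sd
    labels = np.array(["up"] * n_up + ["down"] * n_down
                      + ["ns"] * (p.n_cells - n_up - n_down))
    rng.shuffle(labels)
    for te, sc in zip(event_times, scales):
        mask = t >= te
        kernel = np.exp(-(t[mask] - te) / p.decay_s)
        up_idx = np.nonzero(labels == "up")[0]
        down_idx = np.nonzero(labels == "down")[0]
        if up_idx.size:
            traces[np.ix_(up_idx, np.nonzero(mask)[0])] += amp * sc * kernel
        if down_idx.size:
            traces[np.ix_(down_idx, np.nonzero(mask)[0])] -= amp * sc * kernel

    cell_ids = [f"cell_{i:04d}" for i in range(p.n_cells)]
    events = pd.DataFrame({"time_s": event_times,
                           "label": [p.event_label] * p.n_events})
    rec = CalciumRecording(cell_ids, traces, fps=p.fps, events=events,
                           session_id=session_id)
    truth = {"labels": {c: str(l) for c, l in zip(cell_ids, labels)},
             "event_times_s": event_times.tolist(),
             "amplitude": amp, "event_scales": scales.tolist(),
             "params": asdict(p)}
    return rec, truth


# ---------------------------------------------------------------------------
# calcium I/O dialects (time × cell CSV; simple HDF5 layout)

def write_calcium_csv(rec: CalciumRecording, traces_path: str | Path,
                      events_path: str | Path | None = None) -> Path:
    df = pd.DataFrame(rec.traces.T, columns=rec.cell_ids)
    df.insert(0, "time_s", np.arange(rec.traces.shape[1]) / rec.fps)
    df.to_csv(traces_path, index=False)
    if events_path is not None:
        rec.events.to_csv(events_path, index=False)
    return Path(traces_path)


def read_calcium_csv(traces_path: str | Path,
                     events_path: str | Path | None = None,
                     session_id: str = "") -> CalciumRecording:
    df = pd.read_csv(traces_path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError("calcium CSV must have a 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("calcium CSV too short to infer sampling rate")
    fps = 1.0 / float(np.median(np.diff(t)))
    cells = [c for c in df.columns if c != "time_s"]
    events = (pd.read_csv(events_path) if events_path is not None
              else pd.DataFrame(columns=["time_s", "label"]))
    return CalciumRecording(cells, df[cells].to_numpy(dtype=float).T,
                            fps=fps, events=events, session_id=session_id)


def write_calcium_hdf5(rec: CalciumRecording, path: str | Path) -> Path:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces)
        f.create_dataset("cell_ids",
                         data=np.array([c.encode() for c in rec.cell_ids]))
        f.attrs["fps"] = rec.fps
        f.attrs["session_id"] = rec.session_id
        f.create_dataset("event_times", data=rec.events["time_s"].to_numpy(dtype=float))
        f.create_dataset("event_labels",
                         data=np.array([str(l).encode() for l in rec.events["label"]]))
    return Path(path)


def read_calcium_hdf5(path: str | Path) -> CalciumRecording:
    import h5py

    with h5py.File(path, "r") as f:
        traces = np.asarray(f["traces"], dtype=float)
        cells = [c.decode() for c in f["cell_ids"][()]]
        fps = float(f.attrs["fps"])
        session = str(f.attrs.get("session_id", ""))
        events = pd.DataFrame({
            "time_s": np.asarray(f["event_times"], dtype=float),
            "label": [l.decode() for l in f["event_labels"][()]],
        })
    return CalciumRecording(cells, traces, fps=fps, events=events,
                            session_id=session)
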