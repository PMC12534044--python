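"""Parametric stimulus trajectories and controllers of the mechanostimulator.

Trajectory model
----------------
Poke stimuli move the z-axis through a single sine period starting from the
trough: ``height(t) = A (1 - cos(2π t / λ))`` for ``0 ≤ t ≤ λ`` and 0
outside.  ``A`` is half the peak-to-trough excursion, so the tip rises
``2A`` above its start position and crosses the mesh plane ``m`` mm above
the start whenever ``2A > m``.  With the standard pinprick parameters
(A = 8 mm, λ = 0.8 s, m = 14 mm) the apex sits 2 mm above the mesh.

Force stimuli are closed-loop: a ramp that drives commanded force linearly
from ``f_start`` to ``f_end`` over the ramp duration, or a constant-force
hold in which tip velocity is adjusted proportionally to the force error.
Paw withdrawal registers as a sensed-force drop between consecutive control
steps and retracts the stimulus immediately.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .track_io import EventLog, ForceTrace

__all__ = [
    "StimulusProfile",
    "TriggerConfig",
    "ForceControllerConfig",
    "ControllerResult",
    "sine_poke_profile",
    "vfh_press_profile",
    "brush_profile",
    "mesh_crossing_time",
    "trigger_time",
    "above_mesh_duration",
    "apex_sweep_profiles",
    "force_controller_run",
    "session_schedule",
    "habituation_schedule",
    "SchedulingError",
    "ControllerFault",
    "PINPRICK_AMPLITUDE_MM",
    "PINPRICK_WAVELENGTH_S",
    "PINPRICK_MESH_OFFSET_MM",
]

# standard pinprick / cotton-swab delivery parameters
PINPRICK_AMPLITUDE_MM = 8.0
PINPRICK_WAVELENGTH_S = 0.8
PINPRICK_MESH_OFFSET_MM = 14.0

# von Frey press defaults (sine delivery)
VFH_AMPLITUDE_MM = 3.5
VFH_WAVELENGTH_S = 2.2


class SchedulingError(RuntimeError):
    """Trigger cannot be scheduled (profile never crosses the mesh)."""


class ControllerFault(RuntimeError):
    """The force plant returned a non-finite reading."""


@dataclass(frozen=True)
class StimulusProfile:
    """A parametric stimulus tip height-vs-time trajectory.

    ``amplitude_mm`` is half the peak-to-trough excursion of sine kinds;
    ``mesh_offset_mm`` is the mesh plane height above the tip start
    position.  ``height(t)`` returns tip height above the start position.
    """

    kind: str  # sine_poke | vfh_sine | vfh_linear | brush
    amplitude_mm: float = 0.0
    wavelength_s: float = 0.0
    mesh_offset_mm: float = 0.0
    hold_s: float = 0.0
    rise_s: float = 0.0
    retract_s: float = 0.0
    peak_mm: float = 0.0
    radial_amplitude_mm: float = 0.0
    radial_wavelength_s: float = 0.0

    def height(self, t):
        """Tip height above start position, mm; vectorized over ``t``."""
        t = np.asarray(t, dtype=float)
        if self.kind in ("sine_poke", "vfh_sine", "brush"):
            inside = (t >= 0) & (t <= self.wavelength_s)
            h = np.where(
                inside,
                self.amplitude_mm * (1.0 - np.cos(2.0 * np.pi * t / self.wavelength_s)),
                0.0,
            )
        elif self.kind == "vfh_linear":
            h = np.zeros_like(t)
            rise_end = self.rise_s
            hold_end = rise_end + self.hold_s
            ret_end = hold_end + self.retract_s
            rising = (t >= 0) & (t < rise_end)
            h = np.where(rising, self.peak_mm * t / self.rise_s, h)
            h = np.where((t >= rise_end) & (t < hold_end), self.peak_mm, h)
            if self.retract_s > 0:
                retr = (t >= hold_end) & (t < ret_end)
                h = np.where(retr, self.peak_mm * (1.0 - (t - hold_end) / self.retract_s), h)
        else:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        return h if h.shape else float(h)

    def radial(self, t):
        """Radial-axis displacement (brush kind only), mm."""
        if self.kind != "brush":
            return np.zeros_like(np.asarray(t, dtype=float))
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t <= self.radial_wavelength_s)
        return np.where(
            inside,
            self.radial_amplitude_mm
            * (1.0 - np.cos(2.0 * np.pi * t / self.radial_wavelength_s)),
            0.0,
        )

    @property
    def peak_height_mm(self) -> float:
        if self.kind == "vfh_linear":
            return self.peak_mm
        return 2.0 * self.amplitude_mm

    @property
    def duration_s(self) -> float:
        if self.kind == "vfh_linear":
            return self.rise_s + self.hold_s + self.retract_s
        return self.wavelength_s

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "StimulusProfile":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class TriggerConfig:
    """Camera pre-trigger lead before the stimulus crosses the mesh."""

    lead_s: float = 0.025

    def __post_init__(self) -> None:
        if self.lead_s < 0:
            raise ValueError("lead_s must be non-negative")


def sine_poke_profile(amplitude_mm: float = PINPRICK_AMPLITUDE_MM,
                      wavelength_s: float = PINPRICK_WAVELENGTH_S,
                      mesh_offset_mm: float = PINPRICK_MESH_OFFSET_MM) -> StimulusProfile:
    """Single-period sine poke (pinprick / cotton-swab delivery)."""
    if amplitude_mm <= 0 or wavelength_s <= 0 or mesh_offset_mm < 0:
        raise ValueError("invalid sine poke parameters")
    if 2.0 * amplitude_mm <= mesh_offset_mm:
        warnings.warn(
            "profile never crosses the mesh (2A <= mesh offset); "
            "withdrawal latency is undefined for this stimulus", stacklevel=2)
    return StimulusProfile("sine_poke", amplitude_mm=amplitude_mm,
                           wavelength_s=wavelength_s, mesh_offset_mm=mesh_offset_mm)


def vfh_press_profile(kind: str = "vfh_sine", *,
                      amplitude_mm: float = VFH_AMPLITUDE_MM,
                      wavelength_s: float = VFH_WAVELENGTH_S,
                      rise_s: float = 3.0, hold_s: float = 0.0,
                      retract_s: float = 0.2, peak_mm: float = 3.0,
                      mesh_offset_mm: float = 0.14) -> StimulusProfile:
    """von Frey press: sine delivery, or linear rise–hold–fast-retract."""
    if kind == "vfh_sine":
        if amplitude_mm <= 0 or wavelength_s <= 0:
            raise ValueError("invalid vfh_sine parameters")
        return StimulusProfile("vfh_sine", amplitude_mm=amplitude_mm,
                               wavelength_s=wavelength_s, mesh_offset_mm=mesh_offset_mm)
    if kind == "vfh_linear":
        if rise_s <= 0 or hold_s < 0 or retract_s < 0 or peak_mm <= 0:
            raise ValueError("invalid vfh_linear parameters")
        return StimulusProfile("vfh_linear", rise_s=rise_s, hold_s=hold_s,
                               retract_s=retract_s, peak_mm=peak_mm,
                               mesh_offset_mm=mesh_offset_mm)
    raise ValueError(f"unknown vFH kind {kind!r}")


def brush_profile(z_amplitude_mm: float, z_wavelength_s: float,
                  radial_amplitude_mm: float, radial_wavelength_s: float,
                  mesh_offset_mm: float = PINPRICK_MESH_OFFSET_MM) -> StimulusProfile:
    """Dynamic brush: concurrent sines on the z and radial axes."""
    if min(z_amplitude_mm, z_wavelength_s, radial_amplitude_mm,
           radial_wavelength_s) <= 0:
        raise ValueError("brush amplitudes and wavelengths must be positive")
    return StimulusProfile("brush", amplitude_mm=z_amplitude_mm,
                           wavelength_s=z_wavelength_s,
                           radial_amplitude_mm=radial_amplitude_mm,
                           radial_wavelength_s=radial_wavelength_s,
                           mesh_offset_mm=mesh_offset_mm)


def mesh_crossing_time(profile: StimulusProfile, tol_s: float = 1e-6) -> float | None:
    """Earliest t > 0 with height(t) >= mesh offset; None if never reached."""
    m = profile.mesh_offset_mm
    if m <= 0:
        return 0.0
    if profile.peak_height_mm < m:
        return None
    if profile.kind in ("sine_poke", "vfh_sine", "brush"):
        # closed-form bracket on the rising half-period, refined by brentq
        a = profile.amplitude_mm
        lam = profile.wavelength_s
        if profile.peak_height_mm == m:
            return lam / 2.0
        f = lambda t: profile.height(t) - m
        return float(brentq(f, 0.0, lam / 2.0, xtol=tol_s))
    if profile.kind == "vfh_linear":
        return profile.rise_s * m / profile.peak_mm
    raise ValueError(f"unknown profile kind {profile.kind!r}")


def trigger_time(profile: StimulusProfile,
                 trig: TriggerConfig | None = None) -> float:
    """Camera start time: mesh crossing minus the configured lead, floored at 0."""
    trig = trig or TriggerConfig()
    tc = mesh_crossing_time(profile)
    if tc is None:
        raise SchedulingError("profile never crosses the mesh; cannot schedule trigger")
    t = tc - trig.lead_s
    if t < 0:
        warnings.warn("trigger lead exceeds mesh-crossing time; starting at 0",
                      stacklevel=2)
        return 0.0
    return t


def above_mesh_duration(profile: StimulusProfile) -> float:
    """Time the stimulus tip spends at or above the mesh plane."""
    tc = mesh_crossing_time(profile)
    if tc is None:
        return 0.0
    if profile.kind in ("sine_poke", "vfh_sine", "brush"):
        # symmetric about the apex at λ/2
        return profile.wavelength_s - 2.0 * tc
    if profile.kind == "vfh_linear":
        rise_end = profile.rise_s
        m = profile.mesh_offset_mm
        t_down = (rise_end + profile.hold_s
                  + profile.retract_s * (1.0 - m / profile.peak_mm))
        return t_down - tc
    raise ValueError(f"unknown profile kind {profile.kind!r}")


def apex_sweep_profiles(apex_min_mm: float = 1.0, apex_max_mm: float = 5.0,
                        step_mm: float = 0.5,
                        mesh_offset_mm: float = PINPRICK_MESH_OFFSET_MM,
                        above_mesh_duration_s: float | None = None,
                        ) -> list[StimulusProfile]:
    """Family of sine pokes with varied apex and constant above-mesh time.

    For a requested apex ``a`` above the mesh the construction sets
    ``A = (m + a) / 2`` (so the peak ``2A`` sits exactly ``a`` above the
    mesh) and solves the wavelength from the crossing phase
    ``θc = arccos(1 − m/A)``: the above-mesh time of a sine poke is
    ``λ (π − θc) / π``, so ``λ = T·π / (π − θc)`` keeps it equal to the
    common duration ``T``.  By default ``T`` is the above-mesh time of the
    standard pinprick profile.
    """
    if apex_min_mm <= 0 or step_mm <= 0 or apex_max_mm < apex_min_mm:
        raise ValueError("invalid apex sweep bounds")
    span = apex_max_mm - apex_min_mm
    n_steps = round(span / step_mm)
    if abs(n_steps * step_mm - span) > 1e-9:
        raise ValueError("step_mm must divide the apex span")
    if above_mesh_duration_s is None:
        above_mesh_duration_s = above_mesh_duration(sine_poke_profile())
    if above_mesh_duration_s <= 0:
        raise ValueError("above_mesh_duration_s must be positive")
    profiles = []
    for k in range(n_steps + 1):
        a = apex_min_mm + k * step_mm
        amp = (mesh_offset_mm + a) / 2.0
        ratio = mesh_offset_mm / amp
        if ratio >= 2.0:
            raise ValueError(f"infeasible geometry for apex {a} mm (m/A >= 2)")
        theta_c = math.acos(1.0 - ratio)
        lam = above_mesh_duration_s * math.pi / (math.pi - theta_c)
        profiles.append(StimulusProfile("sine_poke", amplitude_mm=amp,
                                        wavelength_s=lam,
                                        mesh_offset_mm=mesh_offset_mm))
    return profiles


# ---------------------------------------------------------------------------
# closed-loop force stimulus

@dataclass(frozen=True)
class ForceControllerConfig:
    """Force-stimulus controller settings.

    Ramp mode drives commanded force linearly from ``f_start_g`` to
    ``f_end_g`` over ``ramp_duration_s``; constant mode holds
    ``set_force_g`` (allowed 0.25–12 g) by adjusting tip velocity
    proportionally to the force error with gain ``gain_mm_per_g_s``.
    A sensed drop of ``withdrawal_drop_g`` within one control step registers
    paw withdrawal; a sensed force at or above ``mesh_force_signature_g``
    with no compliant give is treated as a mesh strike and aborts the trial.
    """

    mode: str = "ramp"  # ramp | constant
    f_start_g: float = 0.5
    f_end_g: float = 8.0
    ramp_duration_s: float = 5.0
    set_force_g: float | None = None
    max_hold_s: float = 5.0
    withdrawal_drop_g: float = 0.3
    mesh_force_signature_g: float = 15.0
    gain_mm_per_g_s: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("ramp", "constant"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ramp":
            if not (self.f_end_g > self.f_start_g > 0):
                raise ValueError("ramp requires f_end_g > f_start_g > 0")
        else:
            if self.set_force_g is None or not (0.25 <= self.set_force_g <= 12.0):
                raise ValueError("constant mode requires set_force_g in [0.25, 12] g")


@dataclass
class ControllerResult:
    """Outcome of one closed-loop force trial."""

    withdrawal_latency_s: float | None
    max_force_g: float
    aborted_on_mesh: bool
    force_trace: ForceTrace
    commanded_g: np.ndarray = field(repr=False, default=None)


def force_controller_run(cfg: ForceControllerConfig,
                         plant: Callable[[float, float, float], float],
                         dt: float = 0.001) -> ControllerResult:
    """Simulate one force-stimulus trial against a paw plant.

    ``plant(t, commanded_g, indentation_mm)`` returns the sensed force in
    grams.  Synthetic plants (rigid, compliant, withdrawing) are provided by
    :mod:`pawkit.synth`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cfg.mode == "ramp":
        t_end = cfg.ramp_duration_s
        rate = (cfg.f_end_g - cfg.f_start_g) / cfg.ramp_duration_s
        command = lambda t: cfg.f_start_g + rate * t
    else:
        t_end = cfg.max_hold_s
        command = lambda t: cfg.set_force_g

    n = int(round(t_end / dt)) + 1
    times = np.arange(n) * dt
    sensed = np.zeros(n)
    commanded = np.zeros(n)
    z = 0.0  # tip indentation, mm
    latency = None
    aborted = False
    prev = None
    i_stop = n - 1
    for i, t in enumerate(times):
        c = command(t)
        commanded[i] = c
        f = plant(t, c, z)
        if not np.isfinite(f):
            raise ControllerFault(f"plant returned non-finite force at t={t:.4f}s")
        sensed[i] = f
        if prev is not None and prev - f >= cfg.withdrawal_drop_g:
            latency = t  # paw withdrew: retract immediately
            i_stop = i
            break
        if f >= cfg.mesh_force_signature_g:
            aborted = True  # mesh strike signature
            i_stop = i
            break
        prev = f
        # advance tip: proportional velocity on force error
        z = max(0.0, z + cfg.gain_mm_per_g_s * (c - f) * dt)
    i_stop = i_stop + 1
    trace = ForceTrace(times[:i_stop], sensed[:i_stop])
    return ControllerResult(
        withdrawal_latency_s=latency,
        max_force_g=float(sensed[:i_stop].max(initial=0.0)),
        aborted_on_mesh=aborted,
        force_trace=trace,
        commanded_g=commanded[:i_stop],
    )


# ---------------------------------------------------------------------------
# session scheduling

def session_schedule(n_true_trials: int, catch_every: int = 3,
                     inter_trial_s: float = 60.0, seed: int = 0,
                     stimulus: str = "pinprick", n_chambers: int = 5,
                     profile: StimulusProfile | None = None) -> EventLog:
    """Interleave true trials with catch trials delivered to open air.

    With ``catch_every = k > 0``, every k-th scheduled trial is a catch
    trial; ``catch_every = 0`` disables catch trials.  Chamber assignment is
    drawn from a seeded generator so schedules are reproducible.
    """
    if n_true_trials < 1:
        raise ValueError("n_true_trials must be >= 1")
    rng = np.random.default_rng(seed)
    params = (profile or sine_poke_profile()).to_json()
    rows = []
    true_done = 0
    pos = 0
    while (true_done < n_true_trials
           or (catch_every > 0 and (pos + 1) % catch_every == 0)):
        pos += 1
        is_catch = catch_every > 0 and pos % catch_every == 0
        if not is_catch:
            true_done += 1
        rows.append({
            "trial_id": f"trial_{pos:03d}",
            "chamber": int(rng.integers(1, n_chambers + 1)),
            "stimulus": stimulus,
            "onset_s": (pos - 1) * inter_trial_s,
            "is_catch": bool(is_catch),
            "params_json": params,
        })
    return EventLog(pd.DataFrame(rows))


def habituation_schedule(n_chambers: int, per_chamber_s: float = 60.0,
                         seed: int = 0) -> pd.DataFrame:
    """Random move/pause/air-stimulus program acclimating mice to device noise.

    Chambers are visited in order; within each chamber a seeded sequence of
    actions from {move, pause, air_stimulus} fills exactly
    ``per_chamber_s`` seconds (the last action is truncated to fit).
    """
    if n_chambers < 1:
        raise ValueError("n_chambers must be >= 1")
    rng = np.random.default_rng(seed)
    actions = ("move", "pause", "air_stimulus")
    rows = []
    t = 0.0
    for chamber in range(1, n_chambers + 1):
        remaining = per_chamber_s
        while remaining > 0:
            action = actions[rng.integers(0, len(actions))]
            dur = min(float(rng.uniform(2.0, 8.0)), remaining)
            rows.append({"chamber": chamber, "action": action,
                         "onset_s": t, "duration_s": dur})
            t += dur
            remaining -= dur
    return pd.DataFrame(rows)
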