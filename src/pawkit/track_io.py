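"""Reading, writing and calibration of pose-tracking and sensor artifacts.

Supported formats
-----------------
* Pose-tracking HDF5, the common animal-pose-tracker analysis layout:
  dataset ``tracks`` with shape (instances, nodes, 2, frames), dataset
  ``point_scores`` with shape (instances, nodes, frames), dataset
  ``node_names`` (byte strings), and a root attribute ``fps``.  Only the
  first instance is read — one paw is tracked per video.
* Flat CSV fallback with columns ``frame,node,x,y,score`` (long format).
* Feature-table CSV (one row per trial), event-log CSV
  (``trial_id,chamber,stimulus,onset_s,is_catch,params_json``) and
  force-trace CSV (``t_s,force_g``).

Coordinates follow the convention x horizontal, y vertical with upward
positive.  Missing detections are kept as NaN with confidence 0 so frame
indices stay aligned to video time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PoseTrack",
    "Calibration",
    "ForceTrace",
    "EventLog",
    "FormatError",
    "SchemaError",
    "CalibrationError",
    "StateError",
    "read_pose_track",
    "write_pose_track",
    "compute_calibration",
    "apply_calibration",
    "write_features_table",
    "read_features_table",
    "write_force_trace",
    "read_force_trace",
    "write_event_log",
    "read_event_log",
]

REQUIRED_NODES = ("heel", "center", "toe")
REFERENCE_NODES = ("objectA", "objectB")


class FormatError(ValueError):
    """File does not match the expected on-disk layout."""


class SchemaError(ValueError):
    """File parses but lacks required content (e.g. a node)."""


class CalibrationError(ValueError):
    """Pixel→mm calibration cannot be computed or applied."""


class StateError(RuntimeError):
    """Operation applied to a track in the wrong pipeline state."""


@dataclass
class PoseTrack:
    """Per-frame 2D node positions with tracking confidence.

    Parameters
    ----------
    node_names : list of str
        Tracked point labels; must include "heel", "center" and "toe".
    coords : ndarray, shape (n_nodes, n_frames, 2)
        x, y positions, px or mm depending on ``units``.
    confidence : ndarray, shape (n_nodes, n_frames)
        Tracker confidence in [0, 1]; 0 marks a missing detection.
    fps : float
        Video frame rate.
    units : {"px", "mm"}
    meta : dict
        Pipeline bookkeeping (applied stages, baseline config, t=0 offset).
    """

    node_names: list[str]
    coords: np.ndarray
    confidence: np.ndarray
    fps: float
    units: str = "px"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_nodes, n_frames, 2)")
        if self.confidence.shape != self.coords.shape[:2]:
            raise ValueError("confidence shape must match coords")
        if len(self.node_names) != self.coords.shape[0]:
            raise ValueError("node_names length must match coords")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.units not in ("px", "mm"):
            raise ValueError(f"unknown units {self.units!r}")
        finite = self.confidence[np.isfinite(self.confidence)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("confidence values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds; t=0 is stimulus motion onset by default."""
        t0 = float(self.meta.get("t0_s", 0.0))
        return t0 + np.arange(self.n_frames) / self.fps

    def node_index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise SchemaError(f"node {name!r} not present in track") from None

    def node_xy(self, name: str) -> np.ndarray:
        """(n_frames, 2) coordinates of one node."""
        return self.coords[self.node_index(name)]

    def node_confidence(self, name: str) -> np.ndarray:
        return self.confidence[self.node_index(name)]

    def copy(self) -> "PoseTrack":
        return replace(
            self,
            node_names=list(self.node_names),
            coords=self.coords.copy(),
            confidence=self.confidence.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class Calibration:
    """Pixel→millimeter scale from two chamber reference points."""

    refA_px: tuple[float, float]
    refB_px: tuple[float, float]
    known_mm: float
    scale: float  # mm per px

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclass
class ForceTrace:
    """Force-sensor time series in grams-force."""

    t: np.ndarray
    force_g: np.ndarray
    resolution_g: float = 0.05  # sensor quantum of the reference device

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.force_g = np.asarray(self.force_g, dtype=float)
        if self.t.shape != self.force_g.shape:
            raise ValueError("t and force_g must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.force_g)):
            raise ValueError("force_g must be finite")


EVENT_LOG_COLUMNS = ["trial_id", "chamber", "stimulus", "onset_s", "is_catch", "params_json"]


@dataclass
class EventLog:
    """Trial records for one testing session."""

    trials: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_LOG_COLUMNS if c not in self.trials.columns]
        if missing:
            raise SchemaError(f"event log missing columns: {missing}")
        if self.trials["trial_id"].duplicated().any():
            raise ValueError("trial_ids must be unique")
        onsets = self.trials["onset_s"].to_numpy(dtype=float)
        if onsets.size > 1 and np.any(np.diff(onsets) < 0):
            raise ValueError("onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_catch(self) -> int:
        return int(self.trials["is_catch"].astype(bool).sum())

    @property
    def n_true(self) -> int:
        return len(self.trials) - self.n_catch


# ---------------------------------------------------------------------------
# pose tracks

def _validate_required_nodes(node_names: Sequence[str]) -> None:
    missing = [n for n in REQUIRED_NODES if n not in node_names]
    if missing:
        raise SchemaError(f"required node(s) absent: {missing}")


def read_pose_track(path: str | Path, dialect: str | None = None,
                    fps: float | None = None) -> PoseTrack:
    """Read a pose track from HDF5 or long-format CSV.

    ``dialect`` is inferred from the file suffix when omitted.  For CSV,
    ``fps`` must be supplied (the flat table carries no rate); for HDF5 it
    is read from the root ``fps`` attribute unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if dialect == "hdf5":
        return _read_pose_hdf5(path, fps)
    if dialect == "csv":
        if fps is None:
            raise ValueError("fps is required for the CSV dialect")
        return _read_pose_csv(path, fps)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_pose_hdf5(path: Path, fps: float | None) -> PoseTrack:
    with h5py.File(path, "r") as f:
        for ds in ("tracks", "point_scores", "node_names"):
            if ds not in f:
                raise FormatError(f"HDF5 file missing dataset {ds!r}")
        tracks = np.asarray(f["tracks"], dtype=float)
        scores = np.asarray(f["point_scores"], dtype=float)
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["node_names"][()]]
        if fps is None:
            if "fps" not in f.attrs:
                raise FormatError("HDF5 file missing 'fps' attribute")
            fps = float(f.attrs["fps"])
        t0_s = float(f.attrs.get("t0_s", 0.0))
    if tracks.ndim != 4 or tracks.shape[2] != 2:
        raise FormatError(
            f"'tracks' must have shape (instances, nodes, 2, frames); got {tracks.shape}")
    coords = np.moveaxis(tracks[0], 1, 2)  # (nodes, frames, 2)
    confidence = scores[0]
    _validate_required_nodes(names)
    confidence = np.where(np.isfinite(confidence), confidence, 0.0)
    missing = ~np.all(np.isfinite(coords), axis=2)
    coords = coords.copy()
    coords[missing] = np.nan
    confidence = np.where(missing, 0.0, confidence)
    return PoseTrack(names, coords, confidence, fps=fps, units="px",
                     meta={"t0_s": t0_s})


def _read_pose_csv(path: Path, fps: float) -> PoseTrack:
    df = pd.read_csv(path)
    required = {"frame", "node", "x", "y", "score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"CSV missing column(s): {sorted(missing)}")
    names = sorted(df["node"].unique(), key=lambda n: (n not in REQUIRED_NODES, n))
    _validate_required_nodes(names)
    n_frames = int(df["frame"].max()) + 1
    coords = np.full((len(names), n_frames, 2), np.nan)
    confidence = np.zeros((len(names), n_frames))
    for i, name in enumerate(names):
        sub = df[df["node"] == name]
        idx = sub["frame"].to_numpy(dtype=int)
        coords[i, idx, 0] = sub["x"].to_numpy(dtype=float)
        coords[i, idx, 1] = sub["y"].to_numpy(dtype=float)
        confidence[i, idx] = sub["score"].to_numpy(dtype=float)
    missing_mask = ~np.all(np.isfinite(coords), axis=2)
    confidence[missing_mask] = 0.0
    return PoseTrack(names, coords, confidence, fps=fps, units="px")


def write_pose_track(track: PoseTrack, path: str | Path,
                     dialect: str | None = None) -> Path:
    """Write a track in either supported dialect (used by the fixture writer)."""
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if dialect == "hdf5":
        tracks = np.moveaxis(track.coords, 2, 1)[None]  # (1, nodes, 2, frames)
        with h5py.File(path, "w") as f:
            f.create_dataset("tracks", data=tracks)
            f.create_dataset("point_scores", data=track.confidence[None])
            f.create_dataset("node_names",
                             data=np.array([n.encode() for n in track.node_names]))
            f.attrs["fps"] = track.fps
            f.attrs["t0_s"] = float(track.meta.get("t0_s", 0.0))
    else:
        rows = []
        for i, name in enumerate(track.node_names):
            for fr in range(track.n_frames):
                rows.append((fr, name, track.coords[i, fr, 0],
                             track.coords[i, fr, 1], track.confidence[i, fr]))
        pd.DataFrame(rows, columns=["frame", "node", "x", "y", "score"]).to_csv(
            path, index=False)
    return path


# ---------------------------------------------------------------------------
# calibration

def compute_calibration(track: PoseTrack, known_mm: float) -> Calibration:
    """Pixel scale from the chamber reference pair.

    The scale is ``known_mm`` divided by the median over frames of the
    euclidean distance between "objectA" and "objectB" — the median is robust
    to occasional reference mistracking.
    """
    if not known_mm > 0:
        raise ValueError("known_mm must be positive")
    for ref in REFERENCE_NODES:
        if ref not in track.node_names:
            raise CalibrationError(f"reference node {ref!r} absent from track")
    a = track.node_xy("objectA")
    b = track.node_xy("objectB")
    ok = ((track.node_confidence("objectA") > 0)
          & (track.node_confidence("objectB") > 0)
          & np.all(np.isfinite(a), axis=1) & np.all(np.isfinite(b), axis=1))
    if not ok.any():
        raise CalibrationError("reference nodes never confidently tracked")
    dist = np.linalg.norm(a[ok] - b[ok], axis=1)
    med = float(np.median(dist))
    if med <= 0:
        raise CalibrationError("reference nodes coincide; cannot calibrate")
    ref_a = tuple(np.median(a[ok], axis=0))
    ref_b = tuple(np.median(b[ok], axis=0))
    return Calibration(ref_a, ref_b, known_mm, known_mm / med)


def apply_calibration(track: PoseTrack, cal: Calibration) -> PoseTrack:
    """Convert a pixel-space track to millimeters."""
    if track.units != "px":
        raise StateError("track is already calibrated to mm")
    out = track.copy()
    out.coords = out.coords * cal.scale
    out.units = "mm"
    out.meta.setdefault("stages", []).append("calibrate")
    out.meta["scale_mm_per_px"] = cal.scale
    return out


# ---------------------------------------------------------------------------
# tables

def write_features_table(features: Sequence, path: str | Path) -> Path:
    """One row per trial; columns are the feature-record fields in a fixed order."""
    if not features:
        raise ValueError("features list is empty")
    rows = [f.to_row() if hasattr(f, "to_row") else dict(f) for f in features]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return Path(path)


def read_features_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_force_trace(trace: ForceTrace, path: str | Path) -> Path:
    pd.DataFrame({"t_s": trace.t, "force_g": trace.force_g}).to_csv(
        path, index=False)
    return Path(path)


def read_force_trace(path: str | Path, resolution_g: float = 0.05) -> ForceTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_s", "force_g"):
        if col not in df.columns:
            raise FormatError(f"force trace missing column {col!r}")
    return ForceTrace(df["t_s"].to_numpy(), df["force_g"].to_numpy(), resolution_g)


def write_event_log(log: EventLog, path: str | Path) -> Path:
    log.trials.to_csv(path, index=False, columns=EVENT_LOG_COLUMNS)
    return Path(path)


def read_event_log(path: str | Path) -> EventLog:
    df = pd.read_csv(path, dtype={"params_json": str})
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event log missing column(s): {missing}")
    df["is_catch"] = df["is_catch"].astype(bool)
    df["params_json"] = df["params_json"].fillna("{}")
    return EventLog(df)


def params_from_json(s: str) -> dict:
    """Decode the stimulus-parameter payload stored in an event log row."""
    return json.loads(s) if isinstance(s, str) and s.strip() else {}
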