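"""Peri-event analysis of cell-resolved calcium traces.

Traces are aligned to stimulus events and each cell's activity in the
pre-event window (−2 to 0 s) is compared with the post-event window
(0 to 2 s) across events (Wilcoxon signed-rank on per-event means) to label
cells up-, down- or non-regulated.  Random background events drawn away
from true stimuli calibrate the false-positive level.  For single events,
each population-identified pain cell is z-scored against its −4 to −2 s
baseline and tested (Wilcoxon rank-sum, baseline vs post samples); the
fraction of pain cells whose single-event direction matches their
population label is the per-event regulation fraction, which is then
correlated with the withdrawal behavior features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "CalciumRecording",
    "PeriEventConfig",
    "CellClassification",
    "EventRegulation",
    "perievent_stack",
    "classify_cells",
    "sample_background_events",
    "compare_to_background",
    "register_categories",
    "event_regulation_fractions",
    "correlate_fractions_with_behavior",
]

PAIN_LABELS = ("pinprick", "max_pinprick")
TOUCH_LABELS = ("cotton_swab",)


@dataclass
class CalciumRecording:
    """ΔF/F traces (cell × time) with stimulus event annotations."""

    cell_ids: list[str]
    traces: np.ndarray
    fps: float
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["time_s", "label"]))
    session_id: str = ""

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2 or self.traces.shape[0] != len(self.cell_ids):
            raise ValueError("traces must be (n_cells, n_samples)")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if len(self.events):
            t = self.events["time_s"].to_numpy(dtype=float)
            if t.min() < 0 or t.max() > self.duration_s:
                raise ValueError("event times must lie within the recording")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fps


@dataclass(frozen=True)
class PeriEventConfig:
    """Analysis windows (seconds relative to the event) and test level."""

    pre_window: tuple[float, float] = (-2.0, 0.0)
    post_window: tuple[float, float] = (0.0, 2.0)
    baseline_window: tuple[float, float] = (-4.0, -2.0)
    alpha: float = 0.05
    fdr: bool = False  # Benjamini–Hochberg across cells when True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("pre_window", "post_window", "baseline_window"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must be increasing")

    @property
    def full_window(self) -> tuple[float, float]:
        lo = min(self.baseline_window[0], self.pre_window[0])
        hi = max(self.post_window[1], self.pre_window[1])
        return (lo, hi)


@dataclass
class CellClassification:
    """Per-cell regulation labels with effect sizes and p-values."""

    table: pd.DataFrame  # columns: cell_id, label, effect, p_value

    def __post_init__(self) -> None:
        bad = set(self.table["label"]) - {"up", "down", "ns"}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("cell_id")["label"]

    def fraction(self, label: str) -> float:
        return float((self.table["label"] == label).mean())

    @property
    def n_regulated(self) -> int:
        return int((self.table["label"] != "ns").sum())


@dataclass
class EventRegulation:
    """Per-event fractions of pain cells matching their population label."""

    frac_up_matching: float
    frac_down_matching: float
    frac_total_matching: float
    n_pain_cells: int
    n_up_labeled: int = 0
    n_down_labeled: int = 0


def _window_slice(window: tuple[float, float], rel_time: np.ndarray) -> np.ndarray:
    return (rel_time >= window[0]) & (rel_time < window[1])


def perievent_stack(rec: CalciumRecording, event_times: np.ndarray,
                    window_s: tuple[float, float] = (-4.0, 2.0),
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align trace segments to events.

    Returns ``(stack, rel_time, kept)`` where stack is
    (n_cells, n_kept_events, n_samples) and rel_time is seconds relative to
    the event.  Events whose window extends past a recording edge are
    dropped with a warning.
    """
    lo, hi = window_s
    if not hi > lo:
        raise ValueError("window must be increasing")
    event_times = np.asarray(event_times, dtype=float)
    n_lo = int(round(-lo * rec.fps))
    n_hi = int(round(hi * rec.fps))
    rel_time = np.arange(-n_lo, n_hi + 1) / rec.fps
    n_samples = rec.traces.shape[1]
    centers = np.round(event_times * rec.fps).astype(int)
    kept = (centers - n_lo >= 0) & (centers + n_hi < n_samples)
    if not kept.all():
        warnings.warn(f"dropped {int((~kept).sum())} event(s) too close to a "
                      "recording edge", stacklevel=2)
    idx = centers[kept]
    stack = np.stack([rec.traces[:, c - n_lo:c + n_hi + 1] for c in idx], axis=1) \
        if idx.size else np.empty((rec.n_cells, 0, len(rel_time)))
    return stack, rel_time, kept


def classify_cells(stack: np.ndarray, rel_time: np.ndarray,
                   cfg: PeriEventConfig | None = None,
                   cell_ids: list[str] | None = None) -> CellClassification:
    """Label cells up/down/ns from paired pre- vs post-event activity.

    Per cell, the mean ΔF/F in the pre and post windows is computed for
    each event and the paired differences are tested with the Wilcoxon
    signed-rank test across events.  Fewer than 5 events yields all-ns with
    a warning; zero-variance cells are ns.
    """
    cfg = cfg or PeriEventConfig()
    n_cells, n_events, _ = stack.shape
    if cell_ids is None:
        cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]
    pre = stack[:, :, _window_slice(cfg.pre_window, rel_time)].mean(axis=2)
    post = stack[:, :, _window_slice(cfg.post_window, rel_time)].mean(axis=2)
    diff = post - pre
    labels = np.full(n_cells, "ns", dtype=object)
    pvals = np.ones(n_cells)
    effects = diff.mean(axis=1) if n_events else np.zeros(n_cells)
    if n_events < 5:
        warnings.warn("fewer than 5 events: all cells labeled ns", stacklevel=2)
    else:
        for i in range(n_cells):
            d = diff[i]
            if np.allclose(d, 0.0):
                continue
            try:
                pvals[i] = stats.wilcoxon(d).pvalue
            except ValueError:
                continue
        signif = pvals < cfg.alpha
        if cfg.fdr:
            signif = multipletests(pvals, alpha=cfg.alpha, method="fdr_bh")[0]
        med = np.median(diff, axis=1)
        labels[signif & (med > 0)] = "up"
        labels[signif & (med < 0)] = "down"
    return CellClassification(pd.DataFrame({
        "cell_id": cell_ids, "label": labels,
        "effect": effects, "p_value": pvals,
    }))


def sample_background_events(rec: CalciumRecording, n: int,
                             exclusion_s: float = 6.0, seed: int = 0,
                             window_s: tuple[float, float] = (-4.0, 2.0),
                             ) -> np.ndarray:
    """Random background times away from true events and recording edges.

    Draws ``n`` uniform times from the eligible interior (at least
    ``exclusion_s`` from every true event, window fully inside the
    recording), enforcing a minimum spacing of one window span between
    draws.  Seeded and reproducible.
    """
    lo, hi = window_s
    span = hi - lo
    rng = np.random.default_rng(seed)
    dt = 1.0 / rec.fps
    grid = np.arange(-lo + dt, rec.duration_s - hi - dt, dt)
    eligible = np.ones(grid.size, dtype=bool)
    if len(rec.events):
        for te in rec.events["time_s"].to_numpy(dtype=float):
            eligible &= np.abs(grid - te) >= exclusion_s
    times = []
    for _ in range(n):
        avail = np.nonzero(eligible)[0]
        if avail.size == 0:
            raise ValueError(
                f"cannot place {n} background events: eligible time exhausted "
                f"after {len(times)} draws")
        pick = grid[rng.choice(avail)]
        times.append(pick)
        eligible &= np.abs(grid - pick) >= span
    return np.sort(np.asarray(times))


def compare_to_background(class_stim: CellClassification,
                          class_bg: CellClassification) -> pd.DataFrame:
    """Regulated-cell counts for stimulus vs background, with a two-proportion test."""
    if len(class_stim.table) == 0:
        raise ValueError("empty cell set")
    if len(class_stim.table) != len(class_bg.table):
        raise ValueError("stimulus and background classifications must share cells")
    rows = []
    n = len(class_stim.table)
    for name, cls in (("stimulus", class_stim), ("background", class_bg)):
        rows.append({
            "condition": name,
            "n_cells": n,
            "n_up": int((cls.table["label"] == "up").sum()),
            "n_down": int((cls.table["label"] == "down").sum()),
            "n_regulated": cls.n_regulated,
            "frac_regulated": cls.n_regulated / n,
        })
    counts = np.array([rows[0]["n_regulated"], rows[1]["n_regulated"]])
    if counts.sum() in (0, 2 * n):
        p = 1.0
    else:
        _, p = proportions_ztest(counts, np.array([n, n]))
    out = pd.DataFrame(rows)
    out["p_two_proportion"] = p
    return out


def register_categories(day_classifications: dict[str, tuple[str, CellClassification]],
                        registration_map: pd.DataFrame) -> pd.DataFrame:
    """Cross-day cell categories: pain, touch, both, or none.

    ``day_classifications`` maps session_id → (stimulus label,
    classification); ``registration_map`` has one row per registered cell
    with column ``global_id`` plus one column per session holding that
    session's cell id (NaN if unmatched).  A cell is *pain* if regulated in
    any pinprick/max-pinprick session and no cotton-swab session, *touch*
    for the converse, *both* if regulated in both stimulus classes.
    Cells unmapped in any session are excluded and counted.
    """
    if "global_id" not in registration_map.columns:
        raise ValueError("registration_map needs a 'global_id' column")
    sessions = [s for s in day_classifications if s in registration_map.columns]
    missing = set(day_classifications) - set(sessions)
    if missing:
        raise ValueError(f"registration_map lacks session column(s): {sorted(missing)}")
    rows = []
    n_excluded = 0
    for _, reg in registration_map.iterrows():
        pain = touch = False
        ok = True
        for sess in sessions:
            cell = reg[sess]
            if pd.isna(cell):
                ok = False
                break
            stim_label, cls = day_classifications[sess]
            lab = cls.labels.get(cell)
            if lab is None:
                ok = False
                break
            regulated = lab in ("up", "down")
            if regulated and stim_label in PAIN_LABELS:
                pain = True
            if regulated and stim_label in TOUCH_LABELS:
                touch = True
        if not ok:
            n_excluded += 1
            continue
        category = ("both" if pain and touch else
                    "pain" if pain else "touch" if touch else "none")
        rows.append({"global_id": reg["global_id"], "category": category})
    out = pd.DataFrame(rows, columns=["global_id", "category"])
    out.attrs["n_excluded"] = n_excluded
    return out


def category_fractions(categories: pd.DataFrame) -> dict[str, float]:
    """Fractions over registered cells of each cross-day category."""
    n = len(categories)
    if n == 0:
        return {k: float("nan") for k in ("pain", "touch", "both", "none")}
    return {k: float((categories["category"] == k).mean())
            for k in ("pain", "touch", "both", "none")}


def event_regulation_fractions(rec: CalciumRecording,
                               pain_cells: CellClassification,
                               event_time: float,
                               cfg: PeriEventConfig | None = None,
                               ) -> EventRegulation:
    """Single-event regulation of population-identified pain cells.

    Each pain cell's segment is z-scored by its −4 to −2 s baseline mean
    and SD; baseline samples are compared with 0 to 2 s samples by the
    Wilcoxon rank-sum test.  The cell matches if its single-event direction
    is significant and agrees with its population label.  Cells with zero
    baseline SD are skipped for the test but kept in the denominators.
    """
    cfg = cfg or PeriEventConfig()
    pain = pain_cells.table[pain_cells.table["label"] != "ns"]
    if len(pain) == 0:
        raise ValueError("no pain-regulated cells supplied")
    cell_index = {c: i for i, c in enumerate(rec.cell_ids)}
    stack, rel_time, kept = perievent_stack(rec, np.array([event_time]),
                                            cfg.full_window)
    if not kept[0]:
        raise ValueError("event window extends past the recording edge")
    base = _window_slice(cfg.baseline_window, rel_time)
    post = _window_slice(cfg.post_window, rel_time)
    n_up = int((pain["label"] == "up").sum())
    n_down = int((pain["label"] == "down").sum())
    match_up = match_down = 0
    for _, row in pain.iterrows():
        i = cell_index.get(row["cell_id"])
        if i is None:
            continue
        seg = stack[i, 0]
        mu, sd = seg[base].mean(), seg[base].std(ddof=1)
        if sd == 0:
            continue  # skipped for the test, kept in the denominator
        z = (seg - mu) / sd
        stat_p = stats.ranksums(z[base], z[post]).pvalue
        if stat_p >= cfg.alpha:
            continue
        direction = "up" if np.median(z[post]) > np.median(z[base]) else "down"
        if direction == row["label"]:
            if direction == "up":
                match_up += 1
            else:
                match_down += 1
    n_pain = len(pain)
    return EventRegulation(
        frac_up_matching=match_up / n_up if n_up else 0.0,
        frac_down_matching=match_down / n_down if n_down else 0.0,
        frac_total_matching=(match_up + match_down) / n_pain,
        n_pain_cells=n_pain, n_up_labeled=n_up, n_down_labeled=n_down,
    )


def correlate_fractions_with_behavior(fractions: pd.DataFrame,
                                      features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-event regulation fractions with behavior.

    Both inputs are per-event tables sharing an index (or row order); every
    (fraction column, feature column) pair is correlated with pairwise NaN
    dropping.  Pairs with fewer than 3 complete events or zero variance are
    reported with NaN statistics.
    """
    if len(fractions) != len(features):
        raise ValueError("fractions and features must describe the same events")
    rows = []
    for fcol in fractions.columns:
        x_all = fractions[fcol].to_numpy(dtype=float)
        for bcol in features.columns:
            y_all = features[bcol].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            x, y = x_all[ok], y_all[ok]
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r = r2 = p = np.nan
            else:
                res = stats.pearsonr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
                r2 = r * r
            rows.append({"fraction": fcol, "feature": bcol, "n": int(ok.sum()),
                         "r": r, "r_squared": r2, "p_value": p})
    return pd.DataFrame(rows)
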