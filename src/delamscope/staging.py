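"""Developmental staging, windowed event counts, and the mosaic ratio.

Embryos are staged on a linear timeline anchored at the frame where the
two contralateral posterior spiracles first meet dorsally (0 min of dorsal
closure; the anchor frame is user/metadata supplied). Delaminations are
counted in half-open minute windows; by default only events in the
[-30, 100) min analysis range enter the statistics. For mosaic
perturbations the per-embryo statistic is the ratio of marker-positive to
marker-negative delaminating cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .movie import TissueMovie

log = logging.getLogger(__name__)

ANALYSIS_RANGE = (-30.0, 100.0)          # minutes of dorsal closure
DEFAULT_WINDOWS = [(-30.0, 30.0), (30.0, 100.0)]
FIG3D_WINDOWS = [(-30.0, 30.0), (30.0, 90.0)]   # early / late figure preset


@dataclass
class StagedTimeline:
    """Linear frame-to-minutes map with t = 0 at ``t0_frame``."""
    t0_frame: int
    dt: float                             # seconds per frame

    def minutes(self, frame) -> float | np.ndarray:
        return (np.asarray(frame, float) - self.t0_frame) * self.dt / 60.0

    def frame_of(self, minutes: float) -> float:
        return self.t0_frame + minutes * 60.0 / self.dt


def make_timeline(movie: TissueMovie, t0_frame: int) -> StagedTimeline:
    """Attach the staging anchor to *movie* and return its timeline."""
    if not 0 <= t0_frame < movie.n_frames:
        raise ConfigurationError(
            f"t0_frame {t0_frame} outside movie of {movie.n_frames} frames")
    movie.t0_frame = t0_frame
    return StagedTimeline(t0_frame=t0_frame, dt=movie.dt)


@dataclass
class WindowCounts:
    """Per-embryo delamination counts in staged minute windows."""
    embryo_id: str
    windows: list[tuple[float, float]]
    counts: list[int]
    total: int                            # events inside any window
    excluded: int = 0                     # events outside all windows


@dataclass
class MosaicRatio:
    """Per-embryo marker-positive / marker-negative delamination ratio."""
    embryo_id: str
    n_pos: int
    n_neg: int

    @property
    def defined(self) -> bool:
        return self.n_neg > 0

    @property
    def ratio(self) -> float:
        return self.n_pos / self.n_neg if self.defined else np.nan

    @property
    def proportion(self) -> float:
        n = self.n_pos + self.n_neg
        return self.n_pos / n if n else np.nan


def _event_times(events, timeline: StagedTimeline | None,
                 by: str) -> np.ndarray:
    """Staged minute times of events given as a DataFrame or event list."""
    if isinstance(events, pd.DataFrame):
        col_map = {"complete": ["t_complete_min", "true_completion_min"],
                   "onset": ["t_onset_min", "true_onset_min"]}
        for col in col_map[by]:
            if col in events.columns:
                return events[col].to_numpy(float)
        raise KeyError(f"no {by}-time column among {list(events.columns)}")
    attr = "t_complete_min" if by == "complete" else "t_onset_min"
    return np.array([getattr(ev, attr) for ev in events], float)


def _usable(events):
    """Drop border-excluded events (DataFrame or event-object list)."""
    if isinstance(events, pd.DataFrame):
        if "border_excluded" in events.columns:
            return events[~events["border_excluded"].astype(bool)]
        return events
    return [ev for ev in events if not ev.border_excluded]


def bin_events(events, timeline: StagedTimeline | None = None,
               windows: list[tuple[float, float]] | None = None,
               embryo_id: str = "embryo", by: str = "complete") -> WindowCounts:
    """Count events per half-open ``[lo, hi)`` minute window.

    Events are timed by completion (default) or onset. Windows must not
    overlap; events outside every window are excluded from the total and
    logged.
    """
    windows = list(windows) if windows is not None else list(DEFAULT_WINDOWS)
    for (lo1, hi1) in windows:
        if hi1 <= lo1:
            raise ConfigurationError(f"empty window [{lo1}, {hi1})")
        for (lo2, hi2) in windows:
            if (lo1, hi1) != (lo2, hi2) and lo1 < hi2 and lo2 < hi1:
                raise ConfigurationError(
                    f"overlapping windows [{lo1},{hi1}) and [{lo2},{hi2})")
    events = _usable(events)
    times = _event_times(events, timeline, by)
    counts = [int(np.sum((times >= lo) & (times < hi))) for lo, hi in windows]
    inside = np.zeros(len(times), bool)
    for lo, hi in windows:
        inside |= (times >= lo) & (times < hi)
    excluded = int((~inside).sum())
    if excluded:
        log.info("%s: %d events outside all windows", embryo_id, excluded)
    return WindowCounts(embryo_id=embryo_id, windows=windows, counts=counts,
                        total=int(inside.sum()), excluded=excluded)


def mosaic_ratio(events, embryo_id: str = "embryo",
                 analysis_range: tuple[float, float] = ANALYSIS_RANGE,
                 by: str = "complete") -> MosaicRatio:
    """Marker-positive vs marker-negative delamination counts per embryo.

    Border-excluded events are omitted; counting is restricted to the
    staged ``analysis_range``. The ratio is undefined (flagged) when no
    marker-negative cell delaminates.
    """
    events = _usable(events)
    times = _event_times(events, None, by)
    if isinstance(events, pd.DataFrame):
        col = "marker" if "marker" in events.columns else "marker_positive"
        marker = events[col].to_numpy()
    else:
        marker = np.array([bool(ev.marker_positive) for ev in events])
    lo, hi = analysis_range
    sel = (times >= lo) & (times < hi)
    n_pos = int(np.sum(sel & (marker == True)))   # noqa: E712
    n_neg = int(np.sum(sel & (marker == False)))  # noqa: E712
    mr = MosaicRatio(embryo_id=embryo_id, n_pos=n_pos, n_neg=n_neg)
    if not mr.defined:
        log.info("%s: mosaic ratio undefined (no marker-negative events)",
                 embryo_id)
    return mr


def cohort_table(items: list[WindowCounts] | list[MosaicRatio],
                 groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy per-embryo table for the statistics stage.

    Window counts yield one row per embryo x window; mosaic ratios one row
    per embryo. Duplicate embryo ids are a validation error.
    """
    if not items:
        return pd.DataFrame(columns=["embryo_id", "group"])
    ids = [it.embryo_id for it in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate embryo ids: {dupes}")
    groups = groups or {}
    rows = []
    if isinstance(items[0], WindowCounts):
        for wc in items:
            for (lo, hi), n in zip(wc.windows, wc.counts):
                rows.append({"embryo_id": wc.embryo_id,
                             "group": groups.get(wc.embryo_id, ""),
                             "window_lo_min": lo, "window_hi_min": hi,
                             "count": n, "total_in_windows": wc.total})
    else:
        for mr in items:
            rows.append({"embryo_id": mr.embryo_id,
                         "group": groups.get(mr.embryo_id, ""),
                         "n_pos": mr.n_pos, "n_neg": mr.n_neg,
                         "ratio": mr.ratio, "proportion": mr.proportion,
                         "defined": mr.defined})
    return pd.DataFrame(rows)
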