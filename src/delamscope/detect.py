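"""Delamination detection, onset timing, and collapse-geometry classification.

A delamination is a track that ends before the movie does with its apical
area collapsed (final area below a quarter of the track median) and
monotonically shrinking over its last frames. Its onset — the switch from
pulsatile area fluctuation to sustained contraction — is timed by fitting
a fifth-degree polynomial to the area trace over a window ending at
completion, and scanning the fitted derivative backwards from completion
for the first point where it exceeds its window mean: contraction keeps
the derivative below the mean, pre-onset pulsation rides above it.

Collapse geometry is read from the first frame after the cell has left the
tissue: a finite new contact between formerly non-adjacent neighbours is a
new-junction delamination; neighbours converging onto a single point is a
rosette (T2-like) delamination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .movie import CellTrack, TissueMovie
from .movie_io import neighbor_graph

log = logging.getLogger(__name__)

ROSETTE = "rosette"
NEW_JUNCTION = "new_junction"
AMBIGUOUS = "ambiguous"


class EstimationError(ValueError):
    """Raised when a series is too short for the requested onset fit."""


@dataclass
class OnsetParams:
    """Settings of the polynomial-derivative onset estimator."""
    poly_degree: int = 5
    fit_window: int = 60          # frames ending at completion
    exceed_rule: str = "strict"   # derivative must strictly exceed the mean
    fallback: str = "window_start"  # or "none"

    def __post_init__(self) -> None:
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if self.fit_window <= self.poly_degree + 1:
            raise ValueError("fit_window must exceed poly_degree + 1")
        if self.fallback not in ("window_start", "none"):
            raise ValueError("fallback must be 'window_start' or 'none'")


@dataclass
class DelaminationEvent:
    """One detected delamination and its measured observables."""
    cell_id: int
    last_frame: int                       # last frame the label is present
    complete_frame: float                 # midpoint of last-present/first-absent
    t_complete_min: float
    onset_frame: int | None = None
    t_onset_min: float | None = None
    onset_fallback_used: bool = False
    geometry: str | None = None           # rosette / new_junction / ambiguous
    aspect_ratio_at_onset: float = np.nan
    marker_positive: bool | None = None
    border_excluded: bool = False
    track: CellTrack | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# onset timing


def onset_of_delamination(area: np.ndarray, frames: np.ndarray | None = None,
                          params: OnsetParams | None = None
                          ) -> tuple[int, bool]:
    """Onset frame of a delaminating cell from its area trace.

    *area* covers the track up to (and including) the last present frame;
    *frames* gives the matching frame indices (defaults to 0..n-1). The
    degree-``poly_degree`` least-squares polynomial is fitted to the last
    ``fit_window`` points (the raw series; the fit is itself the
    smoother), its derivative evaluated at the window's frame times, and
    the window scanned from the penultimate frame backwards for the first
    frame whose derivative strictly exceeds the window-mean derivative.
    If the derivative never exceeds the mean (an exactly linear decline
    forces this), the configured fallback applies and the flag is set.
    """
    params = params or OnsetParams()
    area = np.asarray(area, float)
    if frames is None:
        frames = np.arange(len(area))
    frames = np.asarray(frames, float)
    if len(area) < params.poly_degree + 2:
        raise EstimationError(
            f"need at least {params.poly_degree + 2} points for a degree-"
            f"{params.poly_degree} fit, got {len(area)}")
    w = min(params.fit_window, len(area))
    if w < params.fit_window:
        log.info("onset window shrunk to %d available frames", w)
    f_win, a_win = frames[-w:], area[-w:]

    poly = np.polynomial.Polynomial.fit(f_win, a_win, params.poly_degree)
    deriv = poly.deriv()(f_win)
    m = deriv.mean()
    # guard against numerically flat derivatives (exactly linear input):
    # require exceedance beyond float noise, scaled to the slope magnitude
    tol = 1e-9 * max(abs(m), np.ptp(a_win) / w, 1e-30)
    # the scan starts inside the contraction phase, where the derivative
    # sits below its window mean; fitted-polynomial boundary wiggle right
    # at completion is skipped before looking for the first exceedance
    i = w - 2
    while i >= 0 and not deriv[i] < m - tol:
        i -= 1
    while i >= 0:
        if deriv[i] > m + tol:
            return int(f_win[i]), False
        i -= 1
    if params.fallback == "window_start":
        return int(f_win[0]), True
    raise EstimationError("derivative never exceeded its mean and "
                          "fallback is disabled")


# ---------------------------------------------------------------------------
# detection


def detect_delaminations(tracks: list[CellTrack], movie: TissueMovie,
                         area_collapse_fraction: float = 0.25,
                         monotone_frames: int = 5,
                         onset_params: OnsetParams | None = None,
                         time_onsets: bool = True) -> list[DelaminationEvent]:
    """Detect delaminations among *tracks* and (optionally) time onsets.

    A track qualifies iff it ends before the final movie frame, its final
    area is below ``area_collapse_fraction`` of its median area, and its
    3-frame-median-smoothed area is non-increasing over the last
    ``monotone_frames`` frames. Tracks touching the image border over
    those frames yield events flagged ``border_excluded`` (kept in the
    returned list, excluded from downstream counts). Completion is the
    midpoint between the last present and first absent frame.
    """
    events: list[DelaminationEvent] = []
    last_movie_frame = movie.n_frames - 1
    for tr in tracks:
        if tr.last_frame >= last_movie_frame:
            continue
        med = float(np.nanmedian(tr.area_um2))
        if not tr.area_um2[-1] < area_collapse_fraction * med:
            log.info("track %d ends early but area not collapsed "
                     "(%.1f of median %.1f): not a delamination",
                     tr.cell_id, tr.area_um2[-1], med)
            continue
        k = min(monotone_frames, tr.n_frames)
        smoothed = medfilt(tr.area_um2, 3) if tr.n_frames >= 3 else tr.area_um2
        tail = smoothed[-k:]
        if np.any(np.diff(tail) > 1e-6 * med):
            log.info("track %d: area not monotone over last %d frames",
                     tr.cell_id, k)
            continue
        border = bool(tr.border_contact[-k:].any())
        complete = tr.last_frame + 0.5
        ev = DelaminationEvent(
            cell_id=tr.cell_id, last_frame=tr.last_frame,
            complete_frame=complete,
            t_complete_min=movie.minutes(complete),
            marker_positive=tr.marker_positive,
            border_excluded=border, track=tr)
        if border:
            log.info("event for cell %d touches the border: excluded "
                     "from counts", tr.cell_id)
        if time_onsets:
            try:
                f_on, fb = onset_of_delamination(tr.area_um2, tr.frames,
                                                 onset_params)
            except EstimationError as exc:
                log.warning("cell %d: onset not estimable (%s)",
                            tr.cell_id, exc)
            else:
                ev.onset_frame = f_on
                ev.t_onset_min = movie.minutes(f_on)
                ev.onset_fallback_used = fb
                idx = tr.index_of(f_on)
                ev.aspect_ratio_at_onset = float(tr.aspect_ratio[idx])
        events.append(ev)
    return events


# ---------------------------------------------------------------------------
# geometry classification


def classify_geometry(event: DelaminationEvent, movie: TissueMovie,
                      junction_length_min: float = 4.0,
                      rosette_radius: float = 3.0) -> str:
    """Collapse geometry of one event from the first post-completion frame.

    Among the cell's neighbours at onset, pairs newly adjacent after the
    collapse with a shared boundary of at least ``junction_length_min`` px
    mark a new-junction delamination; failing that, at least four
    neighbours meeting within ``rosette_radius`` px of the collapse point
    mark a rosette. Anything else — including completion on the movie's
    final frame, where no post-completion frame exists — is ambiguous.
    """
    tr = event.track
    if tr is None:
        raise ValueError("event carries no track; classify from detection")
    first_absent = event.last_frame + 1
    if first_absent > movie.n_frames - 1:
        event.geometry = AMBIGUOUS
        return AMBIGUOUS
    f_on = event.onset_frame if event.onset_frame is not None else tr.first_frame
    neighbours = tr.neighbor_ids[tr.index_of(int(f_on))]
    if len(neighbours) < 2:
        event.geometry = AMBIGUOUS
        return AMBIGUOUS

    g_on = neighbor_graph(movie.labels[int(f_on)])
    g_post = neighbor_graph(movie.labels[first_absent])
    best = 0.0
    for u in neighbours:
        for v in neighbours:
            if u >= v or g_on.has_edge(u, v):
                continue
            if g_post.has_edge(u, v):
                best = max(best, g_post[u][v]["length"])
    if best >= junction_length_min:
        event.geometry = NEW_JUNCTION
        return NEW_JUNCTION

    r0, c0 = tr.centroid[-1]
    H, W = movie.frame_shape
    rr, cc = np.ogrid[:H, :W]
    disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= rosette_radius ** 2
    labels_near = {int(v) for v in np.unique(movie.labels[first_absent][disc])}
    if len(labels_near & neighbours) >= 4:
        event.geometry = ROSETTE
        return ROSETTE
    event.geometry = AMBIGUOUS
    return AMBIGUOUS


def classify_all(events: list[DelaminationEvent], movie: TissueMovie,
                 **kwargs) -> list[DelaminationEvent]:
    for ev in events:
        classify_geometry(ev, movie, **kwargs)
    return events


# ---------------------------------------------------------------------------
# isotropy comparison


def isotropy_at_onset(events: list[DelaminationEvent]) -> dict:
    """Aspect-ratio-at-onset samples by geometry class, with a rank-sum test.

    Rosette-collapsing cells are expected to be more isotropic (aspect
    ratio nearer 1) at onset than new-junction cells. Returns the samples,
    the test result (None when either class is empty), and a note.
    """
    from .stats import rank_sum_test

    samples = {}
    for cls in (ROSETTE, NEW_JUNCTION):
        vals = [ev.aspect_ratio_at_onset for ev in events
                if ev.geometry == cls and np.isfinite(ev.aspect_ratio_at_onset)]
        samples[cls] = np.array(vals)
    if samples[ROSETTE].size and samples[NEW_JUNCTION].size:
        test = rank_sum_test(samples[ROSETTE], samples[NEW_JUNCTION])
        note = "rank-sum comparison of aspect ratio at onset"
    else:
        test = None
        note = "comparison skipped: a geometry class is empty"
        log.info(note)
    return {"samples": samples, "test": test, "note": note}


# ---------------------------------------------------------------------------
# event tables


EVENT_COLUMNS = ["cell_id", "t_onset_min", "t_complete_min", "geometry",
                 "ar_at_onset", "marker", "fallback", "border_excluded"]


def events_to_table(events: list[DelaminationEvent]) -> pd.DataFrame:
    rows = [{"cell_id": ev.cell_id, "t_onset_min": ev.t_onset_min,
             "t_complete_min": ev.t_complete_min, "geometry": ev.geometry,
             "ar_at_onset": ev.aspect_ratio_at_onset,
             "marker": ev.marker_positive, "fallback": ev.onset_fallback_used,
             "border_excluded": ev.border_excluded} for ev in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_table(events: list[DelaminationEvent], path) -> pd.DataFrame:
    df = events_to_table(events)
    df.to_csv(path, index=False)
    return df
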