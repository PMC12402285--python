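"""Delamination detection, onset timing, and geometry classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delamscope import SimConfig, TissueMovie
from delamscope.detect import (AMBIGUOUS, DelaminationEvent, EstimationError,
                               OnsetParams, classify_geometry,
                               detect_delaminations, events_to_table,
                               isotropy_at_onset, onset_of_delamination)
from delamscope.movie import CellTrack
from delamscope.synth import simulate_area_series


def _plateau_then_linear(a0=400.0, n_plateau=40, n_decline=40):
    decline = a0 * (1.0 - np.arange(1, n_decline + 1) / n_decline)
    return np.concatenate([np.full(n_plateau, a0), decline[:-1]])


# ---------------------------------------------------------------------------
# onset estimation


def test_exactly_linear_series_forces_fallback():
    area = 400.0 - 5.0 * np.arange(70)
    f_on, fallback = onset_of_delamination(area, params=OnsetParams())
    assert fallback
    assert f_on == 70 - 60          # window start
    with pytest.raises(EstimationError):
        onset_of_delamination(area, params=OnsetParams(fallback="none"))


def test_plateau_kink_located_from_fitted_derivative():
    # plateau at 400 to frame 39, linear decline to zero at frame 80;
    # dense evaluation of the fitted quintic's derivative against its mean
    # puts the onset within two frames of the kink
    area = _plateau_then_linear()
    f_on, fallback = onset_of_delamination(area,
                                           params=OnsetParams(fit_window=60))
    assert not fallback
    assert 38 <= f_on <= 42


def test_onset_invariant_to_shift_and_scale():
    area = _plateau_then_linear()
    ref, _ = onset_of_delamination(area)
    for transformed in (area + 123.4, area * 7.7, area * 0.02 + 55.0):
        got, _ = onset_of_delamination(transformed)
        assert got == ref


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_onset_shift_scale_equivariance_on_noisy_traces(seed):
    tr = simulate_area_series(1, seed=seed)[0]
    ref, fb = onset_of_delamination(tr.area, tr.frames)
    got, fb2 = onset_of_delamination(tr.area * 3.5 + 100.0, tr.frames)
    assert (got, fb2) == (ref, fb)


def test_too_short_series_raises():
    with pytest.raises(EstimationError):
        onset_of_delamination(np.linspace(10, 1, 6))


def test_window_shrinks_to_available_frames():
    area = _plateau_then_linear(n_plateau=10, n_decline=30)
    f_on, _ = onset_of_delamination(area, params=OnsetParams(fit_window=60))
    assert 7 <= f_on <= 13


def test_recovery_on_noisy_programmed_events():
    errs = []
    for seed in (1, 2):
        for tr in simulate_area_series(25, seed=seed):
            f_on, _ = onset_of_delamination(tr.area, tr.frames)
            errs.append(abs(f_on - tr.true_onset_frame))
    assert np.median(errs) <= 2.0


# ---------------------------------------------------------------------------
# detection


def test_programmed_events_detected_with_matching_ids(pipeline):
    gt_ids = set(pipeline.seq.ground_truth.events["cell_id"])
    det_ids = {e.cell_id for e in pipeline.events if not e.border_excluded}
    assert det_ids == gt_ids


def test_persistent_movie_yields_no_events():
    labels = np.tile(np.array([[1, 2], [3, 4]], np.uint16), (6, 1, 1)
                     ).reshape(6, 2, 2)
    movie = TissueMovie(labels=labels, dt=60, pixel_size=1.0)
    tracks = [CellTrack(cell_id=i, first_frame=0, last_frame=5,
                        area_um2=np.full(6, 100.0), centroid=np.zeros((6, 2)),
                        aspect_ratio=np.ones(6), neighbor_ids=[set()] * 6,
                        border_contact=np.zeros(6, bool)) for i in range(1, 5)]
    assert detect_delaminations(tracks, movie) == []


def test_truncated_track_without_collapse_is_not_an_event():
    movie = TissueMovie(labels=np.zeros((20, 4, 4), np.uint16), dt=60,
                        pixel_size=1.0)
    # segmentation loss at 80% of median area: criterion (a) fails
    area = np.full(10, 100.0)
    area[-1] = 80.0
    tr = CellTrack(cell_id=1, first_frame=0, last_frame=9, area_um2=area,
                   centroid=np.zeros((10, 2)), aspect_ratio=np.ones(10),
                   neighbor_ids=[set()] * 10,
                   border_contact=np.zeros(10, bool))
    assert detect_delaminations([tr], movie) == []


def test_border_touching_event_is_flagged_not_counted():
    movie = TissueMovie(labels=np.zeros((20, 4, 4), np.uint16), dt=60,
                        pixel_size=1.0)
    area = np.concatenate([np.full(10, 100.0), np.linspace(90, 5, 8)])
    tr = CellTrack(cell_id=2, first_frame=0, last_frame=17, area_um2=area,
                   centroid=np.zeros((18, 2)), aspect_ratio=np.ones(18),
                   neighbor_ids=[set()] * 18,
                   border_contact=np.ones(18, bool))
    events = detect_delaminations([tr], movie)
    assert len(events) == 1 and events[0].border_excluded


def test_completion_is_midpoint_between_presence_and_absence(pipeline):
    for ev in pipeline.events:
        assert ev.complete_frame == ev.last_frame + 0.5
        assert ev.t_complete_min == pipeline.movie.minutes(ev.complete_frame)


# ---------------------------------------------------------------------------
# geometry classification


def test_programmed_geometries_recovered(pipeline):
    gt = pipeline.seq.ground_truth.events.set_index("cell_id")
    hits = [ev for ev in pipeline.events if not ev.border_excluded]
    agree = np.mean([ev.geometry == gt.loc[ev.cell_id, "geometry"]
                     for ev in hits])
    assert agree >= 0.9


def test_event_completing_on_final_frame_is_ambiguous(pipeline):
    ev = pipeline.events[0]
    short = TissueMovie(labels=pipeline.movie.labels[:ev.last_frame + 1],
                        dt=pipeline.movie.dt,
                        pixel_size=pipeline.movie.pixel_size)
    assert classify_geometry(
        DelaminationEvent(cell_id=ev.cell_id, last_frame=ev.last_frame,
                          complete_frame=ev.complete_frame,
                          t_complete_min=ev.t_complete_min,
                          onset_frame=ev.onset_frame, track=ev.track),
        short) == AMBIGUOUS


# ---------------------------------------------------------------------------
# isotropy comparison


def _event(geometry, ar):
    return DelaminationEvent(cell_id=0, last_frame=0, complete_frame=0.5,
                             t_complete_min=0.0, geometry=geometry,
                             aspect_ratio_at_onset=ar)


def test_rosette_cells_more_isotropic_in_constructed_cohort():
    events = ([_event("rosette", a) for a in (1.0, 1.1, 1.2, 1.05)]
              + [_event("new_junction", a) for a in (2.4, 2.5, 2.6, 2.45)])
    out = isotropy_at_onset(events)
    assert out["samples"]["rosette"].mean() < \
        out["samples"]["new_junction"].mean()
    assert out["test"].p_two_sided < 0.05


def test_single_class_skips_comparison():
    out = isotropy_at_onset([_event("rosette", 1.1)])
    assert out["test"] is None and out["samples"]["rosette"].size == 1


def test_identical_samples_give_p_one():
    events = [_event("rosette", 1.5), _event("new_junction", 1.5)]
    out = isotropy_at_onset(events * 3)
    assert out["test"].p_two_sided == 1.0


def test_generator_makes_new_junction_cells_more_anisotropic(pipeline):
    out = isotropy_at_onset(pipeline.events)
    assert out["samples"]["rosette"].mean() < \
        out["samples"]["new_junction"].mean()


def test_events_table_has_one_row_per_event(pipeline):
    df = events_to_table(pipeline.events)
    assert len(df) == len(pipeline.events)
    assert set(df["geometry"].dropna()) <= {"rosette", "new_junction",
                                            "ambiguous"}
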