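"""Staged timelines, window counts, mosaic ratios, cohort tables."""

import numpy as np
import pandas as pd
import pytest

from delamscope import ConfigurationError, SimConfig, TissueMovie
from delamscope.staging import (DEFAULT_WINDOWS, FIG3D_WINDOWS, MosaicRatio,
                                StagedTimeline, WindowCounts, bin_events,
                                cohort_table, make_timeline, mosaic_ratio)
from delamscope.synth import simulate_cohort


def _events(times, markers=None, border=None):
    n = len(times)
    return pd.DataFrame({
        "t_complete_min": times,
        "t_onset_min": [t - 10 for t in times],
        "marker": markers if markers is not None else [False] * n,
        "border_excluded": border if border is not None else [False] * n,
    })


# ---------------------------------------------------------------------------
# timeline


def test_timeline_arithmetic():
    tl = StagedTimeline(t0_frame=15, dt=120.0)
    assert tl.minutes(30) == 30.0
    assert tl.minutes(15) == 0.0
    assert StagedTimeline(15, 30.0).minutes(13) == -1.0
    assert tl.frame_of(30.0) == 30


def test_make_timeline_attaches_anchor():
    movie = TissueMovie(labels=np.zeros((10, 4, 4), np.uint16), dt=120,
                        pixel_size=0.2)
    tl = make_timeline(movie, 4)
    assert movie.t0_frame == 4 and tl.minutes(4) == 0.0
    with pytest.raises(ConfigurationError):
        make_timeline(movie, 10)


# ---------------------------------------------------------------------------
# binning


def test_events_binned_into_half_open_windows():
    wc = bin_events(_events([-10.0, 5.0, 40.0]), windows=DEFAULT_WINDOWS)
    assert wc.counts == [2, 1] and wc.total == 3 and wc.excluded == 0


def test_boundary_event_falls_in_second_window():
    wc = bin_events(_events([30.0]), windows=DEFAULT_WINDOWS)
    assert wc.counts == [0, 1]


def test_no_events_gives_zero_counts():
    wc = bin_events(_events([]), windows=DEFAULT_WINDOWS)
    assert wc.counts == [0, 0] and wc.total == 0


def test_overlapping_windows_rejected():
    with pytest.raises(ConfigurationError, match="overlap"):
        bin_events(_events([0.0]), windows=[(-30, 30), (20, 90)])


def test_events_outside_all_windows_are_excluded_but_logged():
    wc = bin_events(_events([-50.0, 0.0, 120.0]), windows=DEFAULT_WINDOWS)
    assert wc.counts == [1, 0] and wc.excluded == 2


def test_border_excluded_events_never_counted():
    wc = bin_events(_events([0.0, 10.0], border=[False, True]),
                    windows=DEFAULT_WINDOWS)
    assert wc.total == 1


def test_binning_by_onset_uses_onset_times():
    wc = bin_events(_events([35.0]), windows=DEFAULT_WINDOWS, by="onset")
    assert wc.counts == [1, 0]        # onset = completion - 10 = 25 min


def test_partition_additivity_across_embryos():
    for i, ev in enumerate(simulate_cohort(20, seed=3)):
        parts = bin_events(ev, windows=DEFAULT_WINDOWS, embryo_id=f"e{i}")
        whole = bin_events(ev, windows=[(-30.0, 100.0)], embryo_id=f"e{i}")
        assert sum(parts.counts) == whole.counts[0]
    assert FIG3D_WINDOWS[1] == (30.0, 90.0)   # figure preset, late window


# ---------------------------------------------------------------------------
# mosaic ratio


def test_ratio_of_positive_to_negative_counts():
    mr = mosaic_ratio(_events([0.0] * 6, markers=[True] * 4 + [False] * 2))
    assert (mr.n_pos, mr.n_neg) == (4, 2) and mr.ratio == 2.0


def test_ratio_undefined_without_negative_events():
    mr = mosaic_ratio(_events([0.0, 1.0], markers=[True, True]))
    assert not mr.defined and np.isnan(mr.ratio)


def test_ratio_respects_analysis_range():
    mr = mosaic_ratio(_events([0.0, 150.0], markers=[True, False]))
    assert (mr.n_pos, mr.n_neg) == (1, 0)


def test_null_cohort_median_ratio_near_one():
    embryos = simulate_cohort(200, seed=1, marker_fraction=0.5)
    ratios = [mosaic_ratio(e, f"e{i}").ratio
              for i, e in enumerate(embryos)
              if mosaic_ratio(e, f"e{i}").defined]
    assert 0.8 <= np.median(ratios) <= 1.25


def test_mean_proportion_converges_to_marker_fraction():
    for q in (0.3, 0.5):
        embryos = simulate_cohort(200, seed=2, marker_fraction=q)
        props = [mosaic_ratio(e, f"e{i}").proportion
                 for i, e in enumerate(embryos)]
        assert np.mean(props) == pytest.approx(q, abs=0.05)


def test_hazard_ratio_raises_median_ratio():
    null = simulate_cohort(100, seed=5, marker_fraction=0.5, hazard_ratio=1.0)
    boosted = simulate_cohort(100, seed=5, marker_fraction=0.5,
                              hazard_ratio=3.0)
    med = lambda es: np.median([m.ratio for i, e in enumerate(es)
                                for m in [mosaic_ratio(e, f"e{i}")]
                                if m.defined])
    assert med(boosted) > med(null)


# ---------------------------------------------------------------------------
# cohort table


def test_cohort_table_one_row_per_embryo_and_window():
    wcs = [WindowCounts(f"e{i}", DEFAULT_WINDOWS, [2, 3], 5)
           for i in range(16)]
    groups = {f"e{i}": ("control" if i < 11 else "perturbed")
              for i in range(16)}
    df = cohort_table(wcs, groups)
    assert len(df) == 32
    assert (df["group"] == "perturbed").sum() == 10


def test_cohort_table_round_trips_through_csv(tmp_path):
    mrs = [MosaicRatio(f"e{i}", i + 1, 2) for i in range(5)]
    df = cohort_table(mrs)
    df.to_csv(tmp_path / "m.csv", index=False)
    back = pd.read_csv(tmp_path / "m.csv")
    np.testing.assert_allclose(back["ratio"], df["ratio"])


def test_empty_and_duplicate_inputs():
    assert cohort_table([]).empty
    with pytest.raises(ConfigurationError, match="duplicate"):
        cohort_table([MosaicRatio("e1", 1, 1), MosaicRatio("e1", 2, 2)])
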