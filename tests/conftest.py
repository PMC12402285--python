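"""Shared fixtures: one default synthetic embryo pipeline, reused widely.

The default configuration (100 cells, 10% delaminating, 2-min frames) is
simulated once per session; tests that need variants build their own small
configs.
"""

from dataclasses import dataclass

import pytest

from delamscope import SimConfig
from delamscope.detect import classify_all, detect_delaminations
from delamscope.movie_io import assign_marker, extract_tracks
from delamscope.synth import (build_tissue_geometry, render_movie,
                              simulate_dynamics)


@dataclass
class Pipeline:
    config: SimConfig
    tess: object
    seq: object
    movie: object
    tracks: list
    events: list


def run_pipeline(seed: int, **overrides) -> Pipeline:
    cfg = SimConfig(seed=seed, **overrides)
    tess = build_tissue_geometry(cfg)
    seq = simulate_dynamics(tess, cfg)
    movie = render_movie(seq, cfg)
    tracks = extract_tracks(movie)
    assign_marker(movie, tracks, threshold_rule="ground_truth",
                  ground_truth=seq.ground_truth.cells)
    events = detect_delaminations(tracks, movie)
    classify_all(events, movie)
    return Pipeline(cfg, tess, seq, movie, tracks, events)


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    """Default synthetic embryo, fully analysed (seed 1)."""
    return run_pipeline(seed=1)


@pytest.fixture(scope="session")
def pipelines_1_5(pipeline) -> dict[int, Pipeline]:
    """Default-configuration embryos for seeds 1..5."""
    out = {1: pipeline}
    for seed in range(2, 6):
        out[seed] = run_pipeline(seed=seed)
    return out


@pytest.fixture(scope="session")
def small_tess():
    """A small, fast tessellation for geometry-level tests."""
    cfg = SimConfig(seed=4, n_cells=25, field_size=(160, 160), n_frames=30,
                    t0_frame=5)
    return cfg, build_tissue_geometry(cfg)
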