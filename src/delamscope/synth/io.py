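"""On-disk layout of a synthetic movie: TIFFs, ground-truth CSV, config echo.

Layout under the output directory::

    labels.tif                     multi-page uint16, frame-major
    channels/<name>_t<frame>.tif   one (Z, H, W) z-stack per rendered frame
    ground_truth.csv               programmed events
    cells.csv                      per-cell baseline state
    simconfig.yaml                 config echo (includes the seed)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import tifffile

from ..config import SimConfig
from ..movie import TissueMovie
from .dynamics import FrameSequence, GroundTruth


def write_outputs(movie: TissueMovie, ground_truth: GroundTruth,
                  config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the movie, ground truth and config echo; return the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["labels"] = out / "labels.tif"
    tifffile.imwrite(paths["labels"], movie.labels)

    chan_dir = out / "channels"
    for name, frames in movie.channels.items():
        chan_dir.mkdir(exist_ok=True)
        for f, stack in frames.items():
            p = chan_dir / f"{name}_t{f:04d}.tif"
            tifffile.imwrite(p, stack)
            paths[f"{name}_t{f}"] = p

    paths["ground_truth"] = out / "ground_truth.csv"
    ground_truth.events.to_csv(paths["ground_truth"], index=False)
    paths["cells"] = out / "cells.csv"
    ground_truth.cells.to_csv(paths["cells"], index=False)
    paths["config"] = out / "simconfig.yaml"
    config.save(paths["config"])
    return paths


def read_ground_truth(outdir: str | Path) -> GroundTruth:
    out = Path(outdir)
    return GroundTruth(events=pd.read_csv(out / "ground_truth.csv"),
                       cells=pd.read_csv(out / "cells.csv"))


def read_channels(outdir: str | Path) -> dict[str, dict[int, "np.ndarray"]]:
    """Reload per-frame channel z-stacks written by :func:`write_outputs`."""
    chan_dir = Path(outdir) / "channels"
    channels: dict[str, dict[int, "np.ndarray"]] = {}
    if not chan_dir.is_dir():
        return channels
    for p in sorted(chan_dir.glob("*_t*.tif")):
        name, _, idx = p.stem.rpartition("_t")
        channels.setdefault(name, {})[int(idx)] = tifffile.imread(p)
    return channels


def simulate_movie(config: SimConfig, outdir: str | Path | None = None,
                   channel_frames=None,
                   amplitudes: dict | None = None,
                   ramp_kind: str = "cosine"):
    """Convenience end-to-end generation: geometry -> dynamics -> render.

    Returns ``(movie, frame_sequence)``; writes files when *outdir* given.
    """
    from .geometry import build_tissue_geometry
    from .dynamics import simulate_dynamics
    from .render import render_movie

    tess = build_tissue_geometry(config)
    seq = simulate_dynamics(tess, config, ramp_kind=ramp_kind)
    movie = render_movie(seq, config, channel_frames=channel_frames,
                         amplitudes=amplitudes)
    if outdir is not None:
        write_outputs(movie, seq.ground_truth, config, outdir)
    return movie, seq
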