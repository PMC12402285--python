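"""In-memory containers for tracked label movies and per-cell time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TissueMovie:
    """A segmented, tracked time-lapse movie of an epithelium.

    ``labels`` is a (T, H, W) integer stack; background is 0 and every cell
    carries a persistent positive label. ``channels`` maps a channel name
    (e.g. ``"ecad"``, ``"myoii"``, ``"nls_mch"``) to a per-frame dict of
    (Z, H, W) fluorescence z-stacks — channels need not cover every frame.
    """

    labels: np.ndarray
    dt: float                                  # seconds per frame
    pixel_size: float                          # µm per pixel
    channels: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    t0_frame: int | None = None                # staging anchor (0 min)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (T, H, W) stack")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be positive")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.labels.shape[1:]

    def minutes(self, frame: float) -> float:
        t0 = 0 if self.t0_frame is None else self.t0_frame
        return (frame - t0) * self.dt / 60.0


@dataclass
class CellTrack:
    """One cell's per-frame apical geometry and topology.

    Series are aligned with ``frames = first_frame..last_frame`` and the
    track is contiguous by construction; a label that vanishes and
    reappears is split into fragments with ``split=True``.
    """

    cell_id: int
    first_frame: int
    last_frame: int
    area_um2: np.ndarray                       # µm² per present frame
    centroid: np.ndarray                       # (n, 2) px, (row, col)
    aspect_ratio: np.ndarray                   # major/minor, >= 1
    neighbor_ids: list[set[int]]
    border_contact: np.ndarray                 # bool per frame
    marker_positive: bool | None = None        # unknown until assigned
    fragment: int = 0
    split: bool = False

    def __post_init__(self) -> None:
        n = self.last_frame - self.first_frame + 1
        for name in ("area_um2", "aspect_ratio", "border_contact"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match frame span")

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.first_frame, self.last_frame + 1)

    @property
    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1

    def index_of(self, frame: int) -> int:
        if not self.first_frame <= frame <= self.last_frame:
            raise KeyError(f"frame {frame} outside track "
                           f"[{self.first_frame}, {self.last_frame}]")
        return frame - self.first_frame
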