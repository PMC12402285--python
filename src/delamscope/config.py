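"""Simulation configuration for the synthetic amnioserosa movie generator.

The defaults emulate whole-tissue live imaging of dorsal closure: a field of
~100 pulsatile cells imaged every 2 min with 15 z-sections 1 µm apart, of
which ~10% delaminate within the −30…100 min window of dorsal closure
(t = 0 anchored to the posterior-spiracle meeting, ``t0_frame``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is infeasible."""


@dataclass
class SimConfig:
    """Parameters of one synthetic tissue movie.

    Times are seconds (``dt``, ``pulsation_period``) or minutes
    (onset/duration ranges, which are expressed on the staged timeline where
    ``t0_frame`` maps to 0 min). Lengths are µm or px as noted.
    """

    n_cells: int = 100
    field_size: tuple[int, int] = (400, 400)  # (H, W) px
    pixel_size: float = 0.2  # µm / px
    dt: float = 120.0  # seconds / frame
    n_frames: int = 85
    t0_frame: int = 20  # staging anchor: frame mapped to 0 min
    pulsation_period: float = 240.0  # seconds
    pulsation_amplitude: float = 0.15  # fraction of baseline area
    tissue_contraction: float = 0.10  # fractional area loss over the movie
    delam_fraction: float = 0.10  # fraction of cells that delaminate
    delam_onset_range: tuple[float, float] = (-30.0, 100.0)  # minutes
    contraction_duration_range: tuple[float, float] = (10.0, 20.0)  # minutes
    geometry_mix: float = 0.5  # fraction of events collapsing as rosettes
    new_junction_length: float = 8.0  # residual junction length, px
    marker_mode: str = "stripes"  # "stripes" | "bernoulli"
    marker_fraction: float = 0.5  # P(marker+) in bernoulli mode
    n_stripes: int = 8  # stripe count across the field (stripes mode)
    delam_hazard_ratio: float = 1.0  # relative delamination hazard, marker+
    n_z: int = 15
    z_spacing: float = 1.0  # µm
    apical_plane: int = 4  # z index of peak junctional signal
    noise_sigma: float = 2.0  # additive Gaussian noise, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ConfigurationError("n_cells must be >= 4")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("dt and pixel_size must be positive")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if not 0.0 <= self.delam_fraction <= 1.0:
            raise ConfigurationError("delam_fraction must lie in [0, 1]")
        for name in ("pulsation_amplitude", "geometry_mix", "marker_fraction",
                     "tissue_contraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0 <= self.t0_frame < self.n_frames:
            raise ConfigurationError("t0_frame out of movie range")
        if self.marker_mode not in ("stripes", "bernoulli"):
            raise ConfigurationError("marker_mode must be 'stripes' or 'bernoulli'")
        if self.delam_hazard_ratio <= 0:
            raise ConfigurationError("delam_hazard_ratio must be positive")
        h, w = self.field_size
        if h * w / self.n_cells < 50:
            raise ConfigurationError(
                "field too small: mean cell area below 50 px^2")

    # -- timeline helpers -------------------------------------------------
    def minutes(self, frame: float) -> float:
        """Staged time of *frame* in minutes (t0_frame -> 0)."""
        return (frame - self.t0_frame) * self.dt / 60.0

    def frame_of(self, minutes: float) -> float:
        return self.t0_frame + minutes * 60.0 / self.dt

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_size"] = list(self.field_size)
        d["delam_onset_range"] = list(self.delam_onset_range)
        d["contraction_duration_range"] = list(self.contraction_duration_range)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("field_size", "delam_onset_range",
                    "contraction_duration_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def cytoskeletal_preset(**overrides) -> SimConfig:
    """Fast-acquisition preset: 30-s frames, 10 z-sections 1 µm apart.

    Used for pulsation-resolved traces (onset timing needs several frames
    per pulsation cycle, which 2-min whole-tissue sampling cannot give).
    """
    base = dict(dt=30.0, n_z=10, n_frames=200, t0_frame=40,
                contraction_duration_range=(10.0, 20.0))
    base.update(overrides)
    return SimConfig(**base)
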