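"""Direct generation of single-cell apical-area time series.

For onset-timing benchmarks the full movie pipeline is unnecessary: the
quantity being estimated is a property of the 1-D area trace. This module
draws traces from the same behavioural model as the tissue simulation —
pulsation about a baseline, then an abrupt switch to unpulsed monotone
contraction — at the fast-acquisition sampling (30-s frames), with
multiplicative measurement noise standing in for segmentation jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ramp


@dataclass
class AreaTrace:
    """One delaminating cell's area trace with its programmed truth."""
    area: np.ndarray                 # µm², indexed by frame 0..n-1
    dt: float                        # seconds per frame
    true_onset_frame: int
    true_completion_frame: int       # first frame with zero area

    @property
    def frames(self) -> np.ndarray:
        return np.arange(len(self.area))


def simulate_area_series(n_events: int, seed: int, *,
                         dt: float = 30.0,
                         pulsation_period: float = 240.0,
                         pulsation_amplitude: float = 0.15,
                         baseline_range: tuple[float, float] = (250.0, 450.0),
                         onset_frame_range: tuple[int, int] = (80, 120),
                         duration_min_range: tuple[float, float] = (10.0, 20.0),
                         noise_cv: float = 0.05,
                         ramp_kind: str = "cosine") -> list[AreaTrace]:
    """Draw *n_events* delaminating-cell traces.

    ``noise_cv`` is the coefficient of variation of multiplicative
    measurement noise (default 5% of the instantaneous area). The trace
    ends at completion: the final stored frame is the last one with
    positive area, matching what a tracked label movie yields.
    """
    rng = np.random.default_rng((seed, 23))
    traces = []
    for _ in range(n_events):
        a0 = rng.uniform(*baseline_range)
        phase = rng.uniform(0, 2 * np.pi)
        f_on = int(rng.integers(onset_frame_range[0],
                                onset_frame_range[1] + 1))
        dur = rng.uniform(*duration_min_range)
        f_comp = f_on + max(2, int(round(dur * 60.0 / dt)))

        f = np.arange(f_comp)
        omega = 2 * np.pi * dt / pulsation_period
        area = a0 * (1.0 + pulsation_amplitude * np.sin(omega * f + phase))
        a_on = area[f_on]
        u = (f[f_on:] - f_on) / (f_comp - f_on)
        area[f_on:] = a_on * ramp(u, ramp_kind)
        if noise_cv > 0:
            area = area * (1.0 + noise_cv * rng.standard_normal(len(area)))
        area = np.clip(area, 1e-3, None)
        traces.append(AreaTrace(area=area, dt=dt, true_onset_frame=f_on,
                                true_completion_frame=f_comp))
    return traces
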