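"""Quantify junctional MyoII with the dilated E-cadherin mask protocol.

Renders two cohorts of frames that differ only by a planted 2x MyoII
contrast, then recovers the contrast: rank z-planes by E-cadherin
brightness, max-project the two most apical bright planes, threshold to a
junctional mask, dilate by 2 px, transfer to the MyoII projection.
"""

import numpy as np

from delamscope import SimConfig
from delamscope.intensity import MaskParams, measure_junctional_intensity
from delamscope.synth import build_tissue_geometry, render_movie, \
    simulate_dynamics

config = SimConfig(seed=3, n_frames=10, t0_frame=2, delam_fraction=0.0)
seq = simulate_dynamics(build_tissue_geometry(config), config)
frames = range(0, 10, 2)
bright = render_movie(seq, config, channel_frames=frames,
                      channels=("ecad", "myoii"),
                      amplitudes={"myoii": {"junctional": 300.0,
                                            "blob": 100.0}})
dim = render_movie(seq, config, channel_frames=frames,
                   channels=("ecad", "myoii"),
                   amplitudes={"myoii": {"junctional": 150.0,
                                         "blob": 50.0}})

params = MaskParams(dilation_radius=2)
res = measure_junctional_intensity(bright, 0, mask_params=params)
print(f"frame 0: planes {res.selected_planes} selected, "
      f"{res.threshold_method} threshold {res.threshold:.1f}, "
      f"mask {res.mask_area_px} px")
hi = [measure_junctional_intensity(bright, f, mask_params=params).mean
      for f in frames]
lo = [measure_junctional_intensity(dim, f, mask_params=params).mean
      for f in frames]
print(f"mean junctional intensity: bright {np.mean(hi):.1f} vs "
      f"dim {np.mean(lo):.1f}")
print(f"recovered enrichment ratio: {np.mean(hi) / np.mean(lo):.2f} "
      "(planted 2.0)")
print("\nThe ratio shows how well the mask protocol isolates junctional "
      "signal; residual shortfall from 2.0 is the camera offset shared by "
      "both cohorts.")
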