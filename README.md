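# delamscope

Quantification of apoptotic cell delamination in epithelial time-lapse
movies, built around the Drosophila amnioserosa during dorsal closure.

During dorsal closure, amnioserosa cells pulse — their apical area
fluctuates with the periodic contractions of the medioapical actomyosin
cortex — and roughly 10% of them abruptly stop pulsing, contract their
apical surface to nothing, and leave the epithelium basally. `delamscope`
turns segmented, tracked label movies of such a tissue into the
quantities this biology is measured by:

- **event detection** — a track that ends before the movie does, with its
  apical area collapsed below a quarter of its median and shrinking
  monotonically over its final frames, is a delamination; cells touching
  the image border are flagged and excluded from counts;
- **onset timing** — the switch from pulsatile to contracting behaviour is
  timed by fitting a fifth-degree polynomial to the cell's area trace
  A(t) over a window ending at completion and scanning its derivative
  A′(t) in reverse for the first point exceeding the window-mean
  derivative;
- **collapse geometry** — a delamination either ends in a rosette (the
  neighbours' vertices converge onto one multicellular vertex, a
  T2-like transition) or leaves a *new junction*, a finite contact
  between two formerly non-adjacent neighbours; the classifier reads the
  contact pattern from the first frame after the cell is gone;
- **staging and counting** — embryos are staged with t = 0 at the meeting
  of the posterior spiracles, and delaminations are counted in half-open
  minute windows (default early [−30, 30) and late [30, 100));
- **mosaic ratio** — under striped (mosaic) perturbations, the per-embryo
  ratio of marker-positive to marker-negative delaminating cells;
- **junctional intensity** — fluorescence of a measured channel (e.g.
  MyoII) inside a binary junctional mask built from the E-cadherin
  channel: the 2–3 most apical bright z-planes are max-projected,
  thresholded, and dilated by 2 px;
- **statistics** — an exact Wilcoxon–Mann–Whitney rank-sum test (full
  enumeration with midranks for ties for pooled n ≤ 16, tie- and
  continuity-corrected normal approximation beyond) and an
  embryo-clustered permutation test for per-embryo summaries.

Raw movies of this kind are rarely public, so the package ships a
first-class synthetic generator (`delamscope.synth`): a relaxed-Voronoi
tissue advanced as a shared-vertex mesh with pulsatile cells, programmed
rosette and new-junction collapses, striped or Bernoulli marker
expression, and two-channel z-stack rendering with a depth-blurred apical
peak — all with a ground-truth event table, so every estimator above can
be validated by parameter recovery.

## Worked example

```python
import numpy as np
from delamscope import SimConfig
from delamscope.synth import simulate_movie
from delamscope.movie_io import extract_tracks
from delamscope.detect import detect_delaminations, classify_all

config = SimConfig(seed=2)            # 100 cells, 10% delaminate, dt = 2 min
movie, seq = simulate_movie(config)
tracks = extract_tracks(movie)
events = detect_delaminations(tracks, movie)
classify_all(events, movie)

gt = seq.ground_truth.events.set_index("cell_id")
found = {e.cell_id: e for e in events if not e.border_excluded}
tp = set(found) & set(gt.index)
print(f"precision {len(tp)/len(found):.2f}  recall {len(tp)/len(gt):.2f}")
errs = [abs(found[c].onset_frame - gt.loc[c, "onset_frame"]) for c in tp]
print(f"median onset error: {np.median(errs):.1f} frames")
```

prints

```
precision 1.00  recall 1.00
median onset error: 3.0 frames
```

— all ten programmed delaminations are found with no false positives, and
the estimated pulsation-to-contraction switch lands within a few 2-min
frames of the programmed one. The `examples/` directory holds one short
script per capability (generation, detection, onset timing, staging and
mosaic statistics, junctional intensity), each printing the numbers it
computes and what they mean. A thin CLI mirrors the library:
`delamscope simulate|track|detect|stage|intensity|run-all`.

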