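"""Kinematic simulation of pulsatile cells and programmed delaminations.

Cells oscillate around their baseline apical area (periodic contractions of
the actomyosin cortex are modelled as a sinusoidal area factor with a
random phase per cell) on top of a slow tissue-wide contraction. A
programmed fraction of cells abruptly stops pulsating at its onset time and
contracts monotonically to zero area at its completion time, either
isotropically (rosette / T2-like collapse: every neighbour contact shrinks
onto a single multicellular vertex) or anisotropically (new-junction
collapse: the cell shrinks onto a segment of its long axis, leaving a
finite contact between two formerly non-adjacent neighbours).

The tissue is advanced as a shared-vertex mesh: each free vertex is the
average of the affine targets of the cells that contain it, so the
tessellation tiles the field at every frame by construction. Once a cell
passes its onset, its vertices are driven purely by the cell's own collapse
transform (anchored at the realized onset geometry, so the trajectory is
continuous at onset); when the collapse completes those vertices freeze,
and the neighbours keep the new contact pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import SimConfig
from .geometry import (Tessellation, _polygon_area, _polygon_centroid,
                       polygon_aspect_ratio)

log = logging.getLogger(__name__)

ROSETTE = "rosette"
NEW_JUNCTION = "new_junction"


@dataclass
class DelamEvent:
    """One programmed delamination (frame indices are simulation frames)."""
    cell_id: int
    geometry: str
    onset_frame: int
    completion_frame: int
    marker_positive: bool


@dataclass
class GroundTruth:
    """Programmed-event table plus per-cell baseline state.

    ``events`` columns: cell_id, true_onset_min, true_completion_min,
    geometry, marker_positive. ``cells`` columns: cell_id,
    baseline_area_px2, baseline_area_um2, phase, marker_positive, border.
    """
    events: pd.DataFrame
    cells: pd.DataFrame
    rejected: list = field(default_factory=list)

    def alive_at(self, frame: int) -> set[int]:
        gone = set(self.events.loc[self.events["completion_frame"] <= frame,
                                   "cell_id"])
        return set(self.cells["cell_id"]) - gone


def ramp(u: np.ndarray | float, kind: str = "cosine"):
    """Normalised area decay over collapse progress u in [0, 1].

    ``cosine`` (the package default) is a smooth monotone half-cosine from
    1 to 0; ``linear`` is a constant-rate alternative with an abrupt kink
    at onset. Both are strictly decreasing on (0, 1).
    """
    u = np.clip(u, 0.0, 1.0)
    if kind == "linear":
        return 1.0 - u
    if kind == "cosine":
        return 0.5 * (1.0 + np.cos(np.pi * u))
    raise ValueError(f"unknown ramp kind: {kind!r}")


# ---------------------------------------------------------------------------
# planning


def assign_markers(tess: Tessellation, config: SimConfig,
                   rng: np.random.Generator) -> dict[int, bool]:
    """Marker-positive flags: striped domains (default) or Bernoulli."""
    if config.marker_mode == "bernoulli":
        return {cid: bool(rng.random() < config.marker_fraction)
                for cid in tess.cell_ids}
    # stripes of alternating expression along the image columns
    _, W = config.field_size
    width = W / max(1, config.n_stripes)
    out = {}
    for cid in tess.cell_ids:
        stripe = int(tess.centroid(cid)[1] // width)
        out[cid] = stripe % 2 == 0
    return out


def plan_delaminations(tess: Tessellation, config: SimConfig,
                       rng: np.random.Generator,
                       markers: dict[int, bool]) -> tuple[list[DelamEvent], list]:
    """Draw the programmed event table for one movie.

    Delaminating cells are interior and pairwise non-adjacent, sampled with
    probability proportional to the marker hazard ratio. Geometry classes
    honour ``geometry_mix``; rosette collapse requires >= 4 neighbours.
    Planned events whose contraction would run past the penultimate frame
    are rejected and logged (the movie must contain the completed state).
    """
    n_events = int(round(config.delam_fraction * config.n_cells))
    rejected: list = []
    if n_events == 0:
        return [], rejected

    candidates = [c for c in tess.cell_ids if not tess.border[c]]
    weights = np.array([config.delam_hazard_ratio if markers[c] else 1.0
                        for c in candidates], float)
    chosen: list[int] = []
    cand = list(candidates)
    w = weights.copy()
    while cand and len(chosen) < n_events:
        pick = rng.choice(len(cand), p=w / w.sum())
        cell = cand[pick]
        chosen.append(cell)
        blocked = tess.neighbors(cell) | {cell}
        keep = [i for i, c in enumerate(cand) if c not in blocked]
        cand = [cand[i] for i in keep]
        w = w[keep]
    if len(chosen) < n_events:
        rejected.append(("plan", f"only {len(chosen)}/{n_events} events "
                         "placeable under the non-adjacency constraint"))
        log.warning("placed %d of %d planned events", len(chosen), n_events)

    # rosette collapse is observed in isotropic cells, new-junction collapse
    # in anisotropic ones: assign geometry by baseline shape
    n_rosette = int(round(config.geometry_mix * len(chosen)))
    by_shape = sorted(chosen,
                      key=lambda c: polygon_aspect_ratio(tess.polygon(c)))
    rosettes = set(by_shape[:n_rosette])

    lo, hi = config.delam_onset_range
    dlo, dhi = config.contraction_duration_range
    events = []
    for cell in chosen:
        onset_min = rng.uniform(lo, hi)
        dur_min = rng.uniform(dlo, dhi)
        f_on = int(round(config.frame_of(onset_min)))
        f_comp = f_on + max(2, int(round(dur_min * 60.0 / config.dt)))
        if f_on < 1 or f_comp > config.n_frames - 2:
            rejected.append((cell, f"onset {onset_min:.1f} min / completion "
                             f"frame {f_comp} falls outside the movie"))
            log.info("rejected planned event for cell %d", cell)
            continue
        geometry = ROSETTE if cell in rosettes else NEW_JUNCTION
        if geometry == ROSETTE and len(tess.neighbors(cell)) < 4:
            geometry = NEW_JUNCTION
        events.append(DelamEvent(cell, geometry, f_on, f_comp, markers[cell]))
    return events, rejected


# ---------------------------------------------------------------------------
# simulation


@dataclass
class FrameSequence:
    """Per-frame polygon sets plus the ground truth that generated them."""
    polygons: list[dict[int, np.ndarray]]     # frame -> {cell_id: (k, 2)}
    ground_truth: GroundTruth
    config: SimConfig
    tessellation: Tessellation
    collapse_points: dict[int, np.ndarray]    # cell_id -> (2,) final point

    @property
    def n_frames(self) -> int:
        return len(self.polygons)

    def area_series(self, cell_id: int) -> np.ndarray:
        """Exact polygon area (px^2) per frame; NaN once the cell is gone."""
        out = np.full(self.n_frames, np.nan)
        for f, polys in enumerate(self.polygons):
            if cell_id in polys:
                out[f] = _polygon_area(polys[cell_id])
        return out


def _edge_neighbor_map(tess: Tessellation, cell: int) -> dict[int, int | None]:
    """Polygon edge index -> neighbour cell across that edge (None at border)."""
    idx = tess.cells[cell]
    vert_cells: dict[int, set[int]] = {}
    for c in tess.cell_ids:
        for v in tess.cells[c]:
            vert_cells.setdefault(int(v), set()).add(c)
    out: dict[int, int | None] = {}
    k = len(idx)
    for i in range(k):
        a, b = int(idx[i]), int(idx[(i + 1) % k])
        shared = (vert_cells[a] & vert_cells[b]) - {cell}
        out[i] = min(shared) if shared else None
    return out


def _collapse_targets(tess: Tessellation, cell: int, poly_on: np.ndarray,
                      geometry: str, seg_length: float
                      ) -> tuple[np.ndarray, str]:
    """Final vertex positions for a collapsing cell.

    Rosette: every vertex onto the centroid (all neighbour contacts end at
    one multicellular vertex). New junction: two flanking neighbours with
    the longest, mutually non-adjacent shared edges are chosen; each of
    their shared edges maps onto the full residual segment (length
    ``seg_length``, centred on the centroid, perpendicular to the line
    joining the two edges), every other vertex onto the nearer segment
    end — so exactly one finite bicellular contact survives, all other
    neighbours meeting at the segment's endpoints. Falls back to rosette
    when the cell has no pair of non-adjacent neighbours.
    """
    g = _polygon_centroid(poly_on)
    if geometry == ROSETTE:
        return np.tile(g, (len(poly_on), 1)), ROSETTE

    idx = tess.cells[cell]
    k = len(idx)
    edge_nb = _edge_neighbor_map(tess, cell)
    lengths = {i: np.linalg.norm(poly_on[(i + 1) % k] - poly_on[i])
               for i in range(k)}
    best: tuple[float, int, int] | None = None
    for i in range(k):
        for j in range(i + 1, k):
            u, v = edge_nb[i], edge_nb[j]
            if u is None or v is None or u == v:
                continue
            if frozenset((u, v)) in tess.adjacency:
                continue
            score = min(lengths[i], lengths[j])
            if best is None or score > best[0]:
                best = (score, i, j)
    if best is None:
        log.info("cell %d has no non-adjacent neighbour pair: collapsing "
                 "as rosette instead", cell)
        return np.tile(g, (len(poly_on), 1)), ROSETTE

    _, ei, ej = best
    mid_i = 0.5 * (poly_on[ei] + poly_on[(ei + 1) % k])
    mid_j = 0.5 * (poly_on[ej] + poly_on[(ej + 1) % k])
    across = mid_j - mid_i
    across /= max(np.linalg.norm(across), 1e-9)
    d = np.array([-across[1], across[0]])     # segment direction
    half = 0.5 * seg_length * d
    end_neg, end_pos = g - half, g + half

    proj = (poly_on - g) @ d
    targets = np.where(proj[:, None] >= 0, end_pos, end_neg)
    # the two flanking edges must span the whole segment: force their
    # endpoints to opposite ends, ordered by projection
    for e in (ei, ej):
        a, b = e, (e + 1) % k
        if proj[a] <= proj[b]:
            targets[a], targets[b] = end_neg, end_pos
        else:
            targets[a], targets[b] = end_pos, end_neg
    return targets, NEW_JUNCTION


def simulate_dynamics(tess: Tessellation, config: SimConfig,
                      plan: list[DelamEvent] | None = None,
                      markers: dict[int, bool] | None = None,
                      ramp_kind: str = "cosine") -> FrameSequence:
    """Advance the tessellation through ``config.n_frames`` frames."""
    rng = np.random.default_rng((config.seed, 11))
    if markers is None:
        markers = assign_markers(tess, config, rng)
    rejected: list = []
    if plan is None:
        plan, rejected = plan_delaminations(tess, config, rng, markers)

    n_frames = config.n_frames
    V0 = tess.vertices
    H, W = config.field_size
    on_border = ((V0[:, 0] <= 0) | (V0[:, 0] >= H) |
                 (V0[:, 1] <= 0) | (V0[:, 1] >= W))

    cell_ids = tess.cell_ids
    phases = {c: rng.uniform(0, 2 * np.pi) for c in cell_ids}
    centroids0 = {c: _polygon_centroid(tess.polygon(c)) for c in cell_ids}
    vertex_cells: dict[int, list[int]] = {}
    for c in cell_ids:
        for v in tess.cells[c]:
            vertex_cells.setdefault(int(v), []).append(c)

    events = {e.cell_id: e for e in plan}
    omega = 2 * np.pi * config.dt / config.pulsation_period

    pos = V0.copy()
    frozen = on_border.copy()                 # field-edge vertices are pinned
    owner: dict[int, DelamEvent] = {}         # vertex -> collapsing cell
    onset_anchor: dict[int, dict] = {}        # cell -> realized onset geometry
    collapse_points: dict[int, np.ndarray] = {}
    frames: list[dict[int, np.ndarray]] = []

    for f in range(n_frames):
        tfrac = f / max(1, n_frames - 1)
        shrink_global = np.sqrt(1.0 - config.tissue_contraction * tfrac)
        scale = {}
        for c in cell_ids:
            e = events.get(c)
            if e is not None and f > e.onset_frame:
                continue                       # collapse-driven, not free
            a = 1.0 + config.pulsation_amplitude * np.sin(omega * f + phases[c])
            scale[c] = np.sqrt(a) * shrink_global

        new_pos = pos.copy()
        for v, cells_v in vertex_cells.items():
            if frozen[v] or v in owner:
                continue
            free = [c for c in cells_v if c in scale]
            if not free:
                frozen[v] = True               # orphaned: keep last position
                continue
            acc = np.zeros(2)
            for c in free:
                g = centroids0[c]
                acc += g + scale[c] * (V0[v] - g)
            new_pos[v] = acc / len(free)

        # collapse-owned vertices: homotopy from the realized onset shape to
        # the programmed final contact pattern, rescaled each frame so the
        # exact polygon area follows ramp(u) * area-at-onset
        for c, e in events.items():
            if f < e.onset_frame:
                continue
            if f == e.onset_frame and c not in onset_anchor:
                poly_on = new_pos[tess.cells[c]].copy()
                targets, realized = _collapse_targets(
                    tess, c, poly_on, e.geometry, config.new_junction_length)
                e.geometry = realized
                onset_anchor[c] = {"v_on": poly_on,
                                   "targets": targets,
                                   "area_on": _polygon_area(poly_on),
                                   "g": _polygon_centroid(poly_on)}
                for v in tess.cells[c]:
                    owner[int(v)] = e
            if f > e.completion_frame:
                continue                       # vertices already frozen
            anc = onset_anchor[c]
            u = (f - e.onset_frame) / (e.completion_frame - e.onset_frame)
            if u >= 1.0:
                poly = anc["targets"]
            else:
                hom = (1.0 - u) * anc["v_on"] + u * anc["targets"]
                a_hom = _polygon_area(hom)
                r_area = float(ramp(u, ramp_kind))
                s = np.sqrt(r_area * anc["area_on"] / max(a_hom, 1e-9))
                g_h = _polygon_centroid(hom)
                poly = g_h + s * (hom - g_h)
            for v, p in zip(tess.cells[c], poly):
                new_pos[int(v)] = p
            if f == e.completion_frame:        # freeze the collapsed contact
                for v in tess.cells[c]:
                    frozen[int(v)] = True
                    owner.pop(int(v), None)
                collapse_points[c] = anc["g"].copy()

        pos = new_pos
        alive = {c for c in cell_ids
                 if c not in events or f < events[c].completion_frame}
        frames.append({c: pos[tess.cells[c]].copy() for c in alive})

    ev_rows = [{"cell_id": e.cell_id,
                "true_onset_min": config.minutes(e.onset_frame),
                "true_completion_min": config.minutes(e.completion_frame),
                "onset_frame": e.onset_frame,
                "completion_frame": e.completion_frame,
                "geometry": e.geometry,
                "marker_positive": e.marker_positive} for e in plan]
    cols = ["cell_id", "true_onset_min", "true_completion_min", "onset_frame",
            "completion_frame", "geometry", "marker_positive"]
    cell_rows = [{"cell_id": c,
                  "baseline_area_px2": tess.area(c),
                  "baseline_area_um2": tess.area(c) * config.pixel_size ** 2,
                  "phase": phases[c],
                  "marker_positive": markers[c],
                  "border": tess.border[c]} for c in cell_ids]
    gt = GroundTruth(events=pd.DataFrame(ev_rows, columns=cols),
                     cells=pd.DataFrame(cell_rows), rejected=rejected)
    return FrameSequence(polygons=frames, ground_truth=gt, config=config,
                         tessellation=tess, collapse_points=collapse_points)
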