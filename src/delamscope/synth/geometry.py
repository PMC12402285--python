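"""Polygonal tissue geometry: a relaxed Voronoi tessellation of the field.

Sites are laid out on a jittered grid and relaxed with two Lloyd iterations,
which yields the mildly irregular, convex-ish cell shapes typical of a
squamous epithelium. The Voronoi diagram is computed on the sites plus
their four mirror images across the field edges, so every cell of interest
is bounded, cells tile the rectangle exactly, and neighbouring cells share
vertex indices (a requirement for the shared-vertex kinematics downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from ..config import SimConfig, ConfigurationError

MIN_CELL_AREA_PX2 = 50.0


def _polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of an (k, 2) closed-implicit polygon."""
    r, c = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def _polygon_centroid(poly: np.ndarray) -> np.ndarray:
    r, c = poly[:, 0], poly[:, 1]
    cross = r * np.roll(c, -1) - np.roll(r, -1) * c
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return poly.mean(axis=0)
    cr = ((r + np.roll(r, -1)) * cross).sum() / (6.0 * a)
    cc = ((c + np.roll(c, -1)) * cross).sum() / (6.0 * a)
    return np.array([cr, cc])


def polygon_aspect_ratio(poly: np.ndarray) -> float:
    """Major/minor axis ratio of the area-moment ellipse of a polygon."""
    r, c = poly[:, 0], poly[:, 1]
    r1, c1 = np.roll(r, -1), np.roll(c, -1)
    cross = r * c1 - r1 * c
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return np.inf
    gr = ((r + r1) * cross).sum() / (6.0 * a)
    gc = ((c + c1) * cross).sum() / (6.0 * a)
    irr = ((r * r + r * r1 + r1 * r1) * cross).sum() / 12.0 - a * gr * gr
    icc = ((c * c + c * c1 + c1 * c1) * cross).sum() / 12.0 - a * gc * gc
    irc = ((r * c1 + 2 * r * c + 2 * r1 * c1 + r1 * c) * cross).sum() / 24.0 \
        - a * gr * gc
    cov = np.array([[irr, irc], [irc, icc]]) / a
    lam = np.linalg.eigvalsh(cov)
    if lam[0] <= 0:
        return np.inf
    return float(np.sqrt(lam[1] / lam[0]))


@dataclass
class Tessellation:
    """Space-filling polygonal tiling of the imaging field.

    ``vertices`` is shared between cells: each cell is an ordered index
    array into it, and internal edges appear in exactly two cells.
    """

    vertices: np.ndarray                      # (V, 2) float, (row, col)
    cells: dict[int, np.ndarray]              # cell_id -> ordered vertex idx
    sites: np.ndarray                         # (n, 2) generating points
    adjacency: dict[frozenset, float]         # {cell pair} -> edge length px
    border: dict[int, bool]                   # touches the field boundary
    field_size: tuple[int, int]

    def polygon(self, cell_id: int) -> np.ndarray:
        return self.vertices[self.cells[cell_id]]

    def area(self, cell_id: int) -> float:
        return _polygon_area(self.polygon(cell_id))

    def centroid(self, cell_id: int) -> np.ndarray:
        return _polygon_centroid(self.polygon(cell_id))

    def neighbors(self, cell_id: int) -> set[int]:
        out = set()
        for pair in self.adjacency:
            if cell_id in pair:
                out |= pair
        out.discard(cell_id)
        return out

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.cells)


def _jittered_grid(n: int, H: int, W: int, rng: np.random.Generator) -> np.ndarray:
    rows = max(2, int(round(np.sqrt(n * H / W))))
    cols = max(2, int(np.ceil(n / rows)))
    dr, dc = H / rows, W / cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = np.column_stack([(rr.ravel() + 0.5) * dr, (cc.ravel() + 0.5) * dc])
    pts += rng.uniform(-0.35, 0.35, pts.shape) * [dr, dc]
    if len(pts) > n:
        keep = rng.choice(len(pts), size=n, replace=False)
        pts = pts[np.sort(keep)]
    return pts


def _mirror(points: np.ndarray, H: int, W: int) -> np.ndarray:
    p = points
    return np.vstack([
        p,
        p * [-1, 1],                  # across r = 0
        p * [-1, 1] + [2 * H, 0],     # across r = H
        p * [1, -1],                  # across c = 0
        p * [1, -1] + [0, 2 * W],     # across c = W
    ])


def _ordered_region(vor: Voronoi, i: int, site: np.ndarray) -> np.ndarray:
    region = vor.regions[vor.point_region[i]]
    if -1 in region or len(region) < 3:
        raise RuntimeError("unbounded Voronoi region for an interior site")
    idx = np.asarray(region)
    rel = vor.vertices[idx] - site
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
    return idx[order]


def build_tissue_geometry(config: SimConfig, n_lloyd: int = 2) -> Tessellation:
    """Construct the relaxed Voronoi tessellation for *config*.

    Raises :class:`ConfigurationError` when the resulting density leaves
    any cell below the minimum resolvable area (50 px²).
    """
    H, W = config.field_size
    rng = np.random.default_rng(config.seed)
    sites = _jittered_grid(config.n_cells, H, W, rng)

    for _ in range(n_lloyd):
        vor = Voronoi(_mirror(sites, H, W))
        new_sites = np.empty_like(sites)
        for i in range(len(sites)):
            poly = vor.vertices[_ordered_region(vor, i, sites[i])]
            new_sites[i] = _polygon_centroid(poly)
        sites = np.clip(new_sites, [1.0, 1.0], [H - 1.0, W - 1.0])

    vor = Voronoi(_mirror(sites, H, W))
    n = len(sites)

    # remap only the vertices actually used by the n real cells
    used: dict[int, int] = {}
    cells: dict[int, np.ndarray] = {}
    for i in range(n):
        region = _ordered_region(vor, i, sites[i])
        for v in region:
            if v not in used:
                used[v] = len(used)
        cells[i + 1] = np.array([used[v] for v in region])
    vertices = np.empty((len(used), 2))
    for old, new in used.items():
        vertices[new] = vor.vertices[old]
    # snap near-boundary vertices exactly onto the field rectangle
    for axis, lim in ((0, H), (1, W)):
        vertices[np.abs(vertices[:, axis]) < 1e-6, axis] = 0.0
        vertices[np.abs(vertices[:, axis] - lim) < 1e-6, axis] = lim

    adjacency: dict[frozenset, float] = {}
    border = {i + 1: False for i in range(n)}
    for (p1, p2), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        real1, real2 = p1 < n, p2 < n
        if real1 != real2:            # edge against a mirror image => border
            if real1:
                border[p1 + 1] = True
            else:
                border[p2 + 1] = True
            continue
        if not (real1 and real2):
            continue
        if -1 in ridge:
            raise RuntimeError("unbounded internal ridge")
        a, b = vor.vertices[ridge[0]], vor.vertices[ridge[1]]
        adjacency[frozenset((p1 + 1, p2 + 1))] = float(np.linalg.norm(a - b))

    tess = Tessellation(vertices=vertices, cells=cells, sites=sites,
                        adjacency=adjacency, border=border,
                        field_size=(H, W))
    areas = [tess.area(cid) for cid in tess.cell_ids]
    if min(areas) < MIN_CELL_AREA_PX2:
        raise ConfigurationError(
            f"cell density infeasible: smallest cell {min(areas):.1f} px^2 "
            f"< {MIN_CELL_AREA_PX2} px^2; enlarge field_size or reduce n_cells")
    return tess
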