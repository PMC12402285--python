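"""Label-movie ingestion and per-cell track extraction.

Works on pre-tracked label movies (persistent positive integer labels, as
segmentation/tracking tools emit); an IoU-based relinker is available for
label movies without persistent ids. Geometry follows the conventions of
standard image software: areas are pixel counts scaled by the pixel size,
and the aspect ratio is major/minor axis of the second-moment ellipse fit.
Coordinates are 0-based (row, col); time is frames internally and minutes
in written outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import networkx as nx
import numpy as np
import pandas as pd
import tifffile
from skimage.measure import regionprops_table

from .movie import CellTrack, TissueMovie

log = logging.getLogger(__name__)


class MovieFormatError(ValueError):
    """Raised for unreadable or inconsistent label-movie inputs."""


# ---------------------------------------------------------------------------
# reading


def read_label_movie(path: str | Path, dt: float, pixel_size: float,
                     t0_frame: int | None = None) -> TissueMovie:
    """Read a multi-page TIFF or a directory of per-frame images.

    Directory frames are ordered by filename; all frames must share
    dimensions and an integer pixel type.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise MovieFormatError(f"no frame images found in {path}")
        frames = [iio.imread(p) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise MovieFormatError(
                f"mixed frame dimensions in {path}: {sorted(shapes)}")
        labels = np.stack(frames)
    else:
        labels = tifffile.imread(path)
        if labels.ndim == 2:
            labels = labels[None]
        if labels.ndim != 3:
            raise MovieFormatError(
                f"{path}: expected a (T, H, W) stack, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise MovieFormatError(
            f"{path}: label pixels must be integers, got {labels.dtype}; "
            "float-valued images are not label movies")
    return TissueMovie(labels=np.ascontiguousarray(labels), dt=dt,
                       pixel_size=pixel_size, t0_frame=t0_frame)


# ---------------------------------------------------------------------------
# per-frame geometry


def cell_geometry(label_image: np.ndarray, cell_id: int,
                  pixel_size: float) -> tuple[float, np.ndarray, float]:
    """(area µm², centroid (row, col) px, aspect ratio) of one cell.

    The aspect ratio is the major/minor axis length ratio of the ellipse
    with the same second moments as the pixel set.
    """
    mask = label_image == cell_id
    n = int(mask.sum())
    if n == 0:
        raise KeyError(f"cell {cell_id} absent from frame")
    props = regionprops_table(mask.astype(np.uint8),
                              properties=("centroid", "axis_major_length",
                                          "axis_minor_length"))
    centroid = np.array([props["centroid-0"][0], props["centroid-1"][0]])
    minor = props["axis_minor_length"][0]
    major = props["axis_major_length"][0]
    ar = float(major / minor) if minor > 0 else np.nan
    return n * pixel_size ** 2, centroid, ar


def neighbor_graph(label_image: np.ndarray) -> nx.Graph:
    """Cell adjacency with shared-boundary lengths (pixel adjacencies).

    Two labels are neighbours iff their pixels are 4-connected-adjacent,
    either directly or across a single background pixel (a 1-px membrane
    line); the edge weight ``length`` counts such pixel adjacencies.
    """
    pairs = []
    for axis in (0, 1):
        a = np.moveaxis(label_image, axis, 0)
        p, q = a[:-1], a[1:]
        m = (p > 0) & (q > 0) & (p != q)
        pairs.append(np.column_stack([p[m], q[m]]))
        p2, mid, q2 = a[:-2], a[1:-1], a[2:]
        m2 = (p2 > 0) & (q2 > 0) & (p2 != q2) & (mid == 0)
        pairs.append(np.column_stack([p2[m2], q2[m2]]))
    g = nx.Graph()
    g.add_nodes_from(int(v) for v in np.unique(label_image) if v > 0)
    if pairs:
        allp = np.vstack(pairs)
        if len(allp):
            allp.sort(axis=1)
            uniq, counts = np.unique(allp, axis=0, return_counts=True)
            for (u, v), n in zip(uniq, counts):
                g.add_edge(int(u), int(v), length=int(n))
    return g


# ---------------------------------------------------------------------------
# tracking


def _frame_properties(label_image: np.ndarray, pixel_size: float) -> pd.DataFrame:
    props = regionprops_table(label_image,
                              properties=("label", "area", "centroid",
                                          "axis_major_length",
                                          "axis_minor_length"))
    df = pd.DataFrame(props)
    df["area_um2"] = df.pop("area") * pixel_size ** 2
    minor = df["axis_minor_length"].to_numpy()
    major = df["axis_major_length"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["aspect_ratio"] = np.where(minor > 0, major / minor, np.nan)
    return df.set_index("label")


def _border_labels(label_image: np.ndarray) -> set[int]:
    edge = np.concatenate([label_image[0], label_image[-1],
                           label_image[:, 0], label_image[:, -1]])
    return {int(v) for v in np.unique(edge) if v > 0}


def extract_tracks(movie: TissueMovie) -> list[CellTrack]:
    """One contiguous track per persistent label.

    A label absent at some frame and present again later is split into
    fragments, each flagged ``split=True`` (segmentation dropout is not a
    delamination and must not masquerade as one).
    """
    T = movie.n_frames
    per_frame = [_frame_properties(movie.labels[f], movie.pixel_size)
                 for f in range(T)]
    borders = [_border_labels(movie.labels[f]) for f in range(T)]
    graphs = [neighbor_graph(movie.labels[f]) for f in range(T)]

    presence: dict[int, list[int]] = {}
    for f, df in enumerate(per_frame):
        for lbl in df.index:
            presence.setdefault(int(lbl), []).append(f)

    tracks: list[CellTrack] = []
    for lbl, frames_present in sorted(presence.items()):
        runs: list[list[int]] = [[frames_present[0]]]
        for f in frames_present[1:]:
            if f == runs[-1][-1] + 1:
                runs[-1].append(f)
            else:
                runs.append([f])
        if len(runs) > 1:
            log.warning("label %d is non-contiguous: split into %d fragments",
                        lbl, len(runs))
        for k, run in enumerate(runs):
            area = np.array([per_frame[f].loc[lbl, "area_um2"] for f in run])
            cent = np.array([[per_frame[f].loc[lbl, "centroid-0"],
                              per_frame[f].loc[lbl, "centroid-1"]]
                             for f in run])
            ar = np.array([per_frame[f].loc[lbl, "aspect_ratio"] for f in run])
            nbrs = [set(graphs[f].neighbors(lbl)) if lbl in graphs[f] else set()
                    for f in run]
            bc = np.array([lbl in borders[f] for f in run])
            tracks.append(CellTrack(
                cell_id=lbl, first_frame=run[0], last_frame=run[-1],
                area_um2=area, centroid=cent, aspect_ratio=ar,
                neighbor_ids=nbrs, border_contact=bc,
                fragment=k, split=len(runs) > 1))
    return tracks


def relink_labels(labels: np.ndarray, iou_min: float = 0.5) -> np.ndarray:
    """Greedy frame-to-frame relinking for non-persistent label movies.

    Successive frames are matched by intersection-over-union (best pairs
    first, each label matched once, matches below ``iou_min`` discarded);
    unmatched regions start new ids. Returns a relabelled stack.
    """
    out = np.zeros_like(labels)
    out[0] = labels[0]
    next_id = int(labels[0].max()) + 1
    for f in range(1, len(labels)):
        prev, cur = out[f - 1], labels[f]
        cand: list[tuple[float, int, int]] = []
        both = (prev > 0) & (cur > 0)
        pairs, counts = np.unique(
            np.column_stack([prev[both], cur[both]]), axis=0,
            return_counts=True) if both.any() else (np.empty((0, 2), int), [])
        prev_sizes = dict(zip(*np.unique(prev[prev > 0], return_counts=True)))
        cur_sizes = dict(zip(*np.unique(cur[cur > 0], return_counts=True)))
        for (p, c), inter in zip(pairs, counts):
            union = prev_sizes[p] + cur_sizes[c] - inter
            cand.append((inter / union, int(p), int(c)))
        cand.sort(reverse=True)
        used_p: set[int] = set()
        mapping: dict[int, int] = {}
        for iou, p, c in cand:
            if iou < iou_min or p in used_p or c in mapping:
                continue
            mapping[c] = p
            used_p.add(p)
        frame_out = np.zeros_like(cur)
        for c in cur_sizes:
            new = mapping.get(int(c))
            if new is None:
                new = next_id
                next_id += 1
            frame_out[cur == c] = new
        out[f] = frame_out
    return out


# ---------------------------------------------------------------------------
# marker assignment


def assign_marker(movie: TissueMovie, tracks: list[CellTrack],
                  marker_channel: str = "nls_mch",
                  threshold_rule: str | tuple = "otsu",
                  nuclear_radius: float = 3.0,
                  ground_truth: pd.DataFrame | None = None) -> list[CellTrack]:
    """Set ``marker_positive`` on each track from the nuclear channel.

    The per-track statistic is the median, over the first five present
    frames with channel data, of the mean intensity in a disc of
    ``nuclear_radius`` px around the cell centroid at the apical-most
    z-projection. ``threshold_rule``: ``"otsu"`` (split of the per-track
    statistics), ``("fixed", value)``, or ``"ground_truth"`` (bypass: copy
    the generator's marker column, for pipeline tests).
    """
    if threshold_rule == "ground_truth":
        if ground_truth is None:
            raise ValueError("threshold_rule 'ground_truth' needs the table")
        flags = dict(zip(ground_truth["cell_id"],
                         ground_truth["marker_positive"]))
        for tr in tracks:
            tr.marker_positive = bool(flags.get(tr.cell_id, False))
        return tracks

    if marker_channel not in movie.channels or not movie.channels[marker_channel]:
        raise ValueError(f"channel {marker_channel!r} not present in movie")
    stacks = movie.channels[marker_channel]
    proj = {f: s.max(axis=0) for f, s in stacks.items()}
    H, W = movie.frame_shape
    rr, cc = np.ogrid[:H, :W]

    stats = np.full(len(tracks), np.nan)
    for i, tr in enumerate(tracks):
        vals = []
        for f in tr.frames[:5]:
            if f not in proj:
                continue
            r0, c0 = tr.centroid[tr.index_of(f)]
            disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= nuclear_radius ** 2
            if disc.any():
                vals.append(float(proj[f][disc].mean()))
        if vals:
            stats[i] = float(np.median(vals))

    if isinstance(threshold_rule, tuple) and threshold_rule[0] == "fixed":
        thr = float(threshold_rule[1])
    elif threshold_rule == "otsu":
        finite = stats[np.isfinite(stats)]
        if finite.size == 0 or np.ptp(finite) == 0:
            thr = np.inf            # degenerate channel: all negative
        else:
            from skimage.filters import threshold_otsu
            thr = float(threshold_otsu(finite))
    else:
        raise ValueError(f"unknown threshold_rule: {threshold_rule!r}")

    for tr, s in zip(tracks, stats):
        tr.marker_positive = bool(np.isfinite(s) and s > thr)
    return tracks


# ---------------------------------------------------------------------------
# track tables


TRACK_COLUMNS = ["cell_id", "fragment", "frame", "t_min", "area_um2",
                 "aspect_ratio", "n_neighbors", "border", "marker"]


def tracks_to_table(tracks: list[CellTrack], movie: TissueMovie) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            rows.append({
                "cell_id": tr.cell_id, "fragment": tr.fragment,
                "frame": int(f), "t_min": movie.minutes(f),
                "area_um2": tr.area_um2[i],
                "aspect_ratio": tr.aspect_ratio[i],
                "n_neighbors": len(tr.neighbor_ids[i]),
                "border": bool(tr.border_contact[i]),
                "marker": tr.marker_positive,
            })
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks_table(tracks: list[CellTrack], movie: TissueMovie,
                       path: str | Path) -> pd.DataFrame:
    """Long-format per-frame track table; round-trips losslessly."""
    df = tracks_to_table(tracks, movie)
    df.to_csv(path, index=False)
    return df


def read_tracks_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
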