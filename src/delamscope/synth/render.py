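"""Rasterisation of simulated tissue frames into label and fluorescence images.

The junctional channel ("ecad") is a Gaussian ridge along cell boundaries;
the contractility channel ("myoii") combines a junctional component with
medioapical blobs; the nuclear mosaic channel ("nls_mch") marks
marker-positive cells. Channels are rendered as z-stacks whose intensity
follows a Gaussian depth profile peaking at the designated apical plane,
emulating the curvature-blurred acquisition of a live embryo.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import polygon as draw_polygon
from skimage.segmentation import find_boundaries

from ..config import SimConfig
from ..movie import TissueMovie
from .dynamics import FrameSequence

DEFAULT_AMPLITUDES = {
    "ecad": {"background": 8.0, "junctional": 150.0, "blob": 0.0},
    "myoii": {"background": 8.0, "junctional": 75.0, "blob": 50.0},
    "nls_mch": {"background": 4.0, "junctional": 0.0, "blob": 120.0},
}
RIDGE_SIGMA = 1.0      # px, cross-section of the junctional ridge
BLOB_SIGMA = 4.0       # px, medioapical / nuclear blob width
Z_SIGMA = 1.5          # planes, depth-blur of the apical signal


def rasterize_labels(polygons: dict[int, np.ndarray],
                     shape: tuple[int, int]) -> np.ndarray:
    """Label image for one frame; cells drawn in id order, background 0."""
    img = np.zeros(shape, dtype=np.uint16)
    for cid in sorted(polygons):
        poly = polygons[cid]
        if len(poly) < 3:
            continue
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
        img[rr, cc] = cid
    return img


def boundary_mask(label_image: np.ndarray) -> np.ndarray:
    """True junctional pixels: boundaries between labels or against gaps."""
    return find_boundaries(label_image, mode="thick")


def _ridge_image(label_image: np.ndarray) -> np.ndarray:
    bnd = boundary_mask(label_image)
    if not bnd.any():
        return np.zeros(label_image.shape)
    d = distance_transform_edt(~bnd)
    return np.exp(-d * d / (2.0 * RIDGE_SIGMA ** 2))


def _blob_image(centers: list[np.ndarray], shape: tuple[int, int],
                sigma: float = BLOB_SIGMA) -> np.ndarray:
    img = np.zeros(shape)
    if not centers:
        return img
    half = int(np.ceil(4 * sigma))
    for ctr in centers:
        r0, c0 = ctr
        rlo, rhi = max(0, int(r0) - half), min(shape[0], int(r0) + half + 1)
        clo, chi = max(0, int(c0) - half), min(shape[1], int(c0) + half + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi),
                             indexing="ij")
        img[rlo:rhi, clo:chi] += np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2))
    return img


def _z_profile(n_z: int, apical_plane: int) -> np.ndarray:
    z = np.arange(n_z)
    return np.exp(-(z - apical_plane) ** 2 / (2.0 * Z_SIGMA ** 2))


def _centroids(polygons: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    return {cid: poly.mean(axis=0) for cid, poly in polygons.items()}


def render_channel_frame(name: str, label_image: np.ndarray,
                         polygons: dict[int, np.ndarray],
                         markers: dict[int, bool], config: SimConfig,
                         frame: int,
                         amplitudes: dict | None = None) -> np.ndarray:
    """One (Z, H, W) z-stack for *name* at *frame* (seeded noise included)."""
    amp = dict(DEFAULT_AMPLITUDES[name])
    if amplitudes:
        amp.update(amplitudes)
    base = np.zeros(label_image.shape)
    if amp["junctional"]:
        base += amp["junctional"] * _ridge_image(label_image)
    if amp["blob"]:
        cents = _centroids(polygons)
        if name == "nls_mch":
            centers = [c for cid, c in cents.items() if markers.get(cid)]
        else:
            centers = list(cents.values())
        base += amp["blob"] * _blob_image(centers, label_image.shape)

    prof = _z_profile(config.n_z, config.apical_plane)
    stack = amp["background"] + prof[:, None, None] * base[None, :, :]
    if config.noise_sigma > 0:
        chan_key = {"ecad": 1, "myoii": 2, "nls_mch": 3}.get(name, 9)
        rng = np.random.default_rng((config.seed, 101, chan_key, frame))
        stack = stack + rng.normal(0.0, config.noise_sigma, stack.shape)
    return np.clip(stack, 0.0, None).astype(np.float32)


def render_movie(seq: FrameSequence, config: SimConfig | None = None,
                 channels: tuple[str, ...] = ("ecad", "myoii", "nls_mch"),
                 channel_frames: range | list[int] | None = None,
                 amplitudes: dict[str, dict] | None = None) -> TissueMovie:
    """Rasterise a simulated frame sequence into a :class:`TissueMovie`.

    Labels are rendered for every frame; fluorescence z-stacks only for
    ``channel_frames`` (default: the first five frames, which is what
    marker assignment consumes) to keep memory proportional to use.
    """
    config = config or seq.config
    H, W = config.field_size
    labels = np.stack([rasterize_labels(p, (H, W)) for p in seq.polygons])

    markers = dict(zip(seq.ground_truth.cells["cell_id"],
                       seq.ground_truth.cells["marker_positive"]))
    if channel_frames is None:
        channel_frames = range(min(5, seq.n_frames))
    chan_data: dict[str, dict[int, np.ndarray]] = {}
    for name in channels:
        per_frame = {}
        for f in channel_frames:
            per_frame[f] = render_channel_frame(
                name, labels[f], seq.polygons[f], markers, config, f,
                (amplitudes or {}).get(name))
        chan_data[name] = per_frame

    return TissueMovie(labels=labels, dt=config.dt,
                       pixel_size=config.pixel_size, channels=chan_data,
                       t0_frame=config.t0_frame)
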