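"""Junctional fluorescence quantification.

The protocol mirrors standard practice for curved epithelia imaged in z:
rank the z-planes by summed intensity of a junctional reference channel
(E-cadherin), max-project the 2–3 most apical of the brightest planes,
threshold the projection to a binary junctional mask, dilate it by a small
radius (default 2 px) to cover the full junctional signal width, then
transfer the mask to the measured channel (e.g. myosin II) and report the
intensity statistics of the selected pixels. Every run echoes its
parameters so measurements are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

from .movie import TissueMovie


@dataclass
class ProjectionParams:
    """Apical-plane selection settings."""
    n_planes: int = 2                    # 2 or 3 by convention
    reference_channel: str = "ecad"

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")


@dataclass
class MaskParams:
    """Junctional-mask settings; ``threshold`` None means automatic Otsu."""
    threshold: float | None = None
    dilation_radius: int = 2

    def __post_init__(self) -> None:
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")


@dataclass
class IntensityResult:
    """Intensity statistics of the measured channel within the mask."""
    frame: int | None
    mask_area_px: int
    mean: float
    median: float
    integrated: float
    threshold_method: str
    threshold: float
    dilation_radius: int
    selected_planes: tuple[int, ...] = ()
    params: dict = field(default_factory=dict)


def select_apical_planes(zstack: np.ndarray,
                         params: ProjectionParams | None = None
                         ) -> tuple[np.ndarray, tuple[int, ...]]:
    """Max-project the brightest (most apical on ties) reference planes.

    Planes are ranked by summed intensity; ties break toward the lower z
    index (imaging from the apical side, plane 0 is most apical). Returns
    the projection and the selected plane indices, sorted.
    """
    params = params or ProjectionParams()
    if zstack.ndim != 3:
        raise ValueError("zstack must be (Z, H, W)")
    if zstack.shape[0] < params.n_planes:
        raise ValueError(f"stack has {zstack.shape[0]} planes, "
                         f"{params.n_planes} requested")
    sums = zstack.reshape(zstack.shape[0], -1).sum(axis=1)
    order = sorted(range(len(sums)), key=lambda z: (-sums[z], z))
    selected = tuple(sorted(order[:params.n_planes]))
    return zstack[list(selected)].max(axis=0), selected


def make_junctional_mask(reference: np.ndarray,
                         params: MaskParams | None = None
                         ) -> tuple[np.ndarray, dict]:
    """Binary junctional mask from the reference projection.

    Automatic thresholding (Otsu's bimodal split) is the default; a
    constant image cannot be auto-thresholded and raises an error
    directing to a fixed threshold. The mask is dilated with a disc of
    ``dilation_radius`` px (radius 0 leaves the thresholded mask as-is).
    The info dict records method, threshold and mask area.
    """
    params = params or MaskParams()
    if reference.ndim != 2:
        raise ValueError("reference projection must be 2-D")
    if params.threshold is not None:
        thr = float(params.threshold)
        method = "fixed"
    else:
        if np.ptp(reference) == 0:
            raise ValueError(
                "constant reference image: automatic thresholding is "
                "undefined; pass a fixed MaskParams(threshold=...) instead")
        thr = float(threshold_otsu(np.asarray(reference, float)))
        method = "otsu"
    mask = reference > thr
    if params.dilation_radius > 0:
        mask = dilation(mask, disk(params.dilation_radius))
    info = {"threshold_method": method, "threshold": thr,
            "dilation_radius": params.dilation_radius,
            "mask_area_px": int(mask.sum())}
    return mask, info


def junctional_intensity(measured: np.ndarray, mask: np.ndarray,
                         info: dict | None = None,
                         frame: int | None = None) -> IntensityResult:
    """Mean/median/integrated intensity of *measured* within *mask*."""
    if measured.shape != mask.shape:
        raise ValueError("measured image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty junctional mask: nothing to measure")
    vals = np.asarray(measured, float)[mask]
    info = info or {}
    return IntensityResult(
        frame=frame, mask_area_px=int(mask.sum()),
        mean=float(vals.mean()), median=float(np.median(vals)),
        integrated=float(vals.sum()),
        threshold_method=info.get("threshold_method", "external"),
        threshold=float(info.get("threshold", np.nan)),
        dilation_radius=int(info.get("dilation_radius", 0)),
        selected_planes=tuple(info.get("selected_planes", ())),
        params=dict(info))


def measure_junctional_intensity(movie: TissueMovie, frame: int,
                                 measured_channel: str = "myoii",
                                 proj_params: ProjectionParams | None = None,
                                 mask_params: MaskParams | None = None,
                                 cell_mask: np.ndarray | None = None
                                 ) -> IntensityResult:
    """Full protocol on one frame of a movie.

    Selects apical planes on the reference channel, projects both channels
    over those planes, builds the dilated junctional mask from the
    reference, and measures the measured-channel projection inside it.
    ``cell_mask`` optionally intersects the junctional mask with a cell
    footprint (per-cell variant).
    """
    proj_params = proj_params or ProjectionParams()
    ref_name = proj_params.reference_channel
    for name in (ref_name, measured_channel):
        if name not in movie.channels or frame not in movie.channels[name]:
            raise ValueError(f"channel {name!r} has no z-stack at frame {frame}")
    ref_proj, planes = select_apical_planes(movie.channels[ref_name][frame],
                                            proj_params)
    meas_proj = movie.channels[measured_channel][frame][list(planes)].max(axis=0)
    mask, info = make_junctional_mask(ref_proj, mask_params)
    if cell_mask is not None:
        mask = mask & cell_mask
    info["selected_planes"] = planes
    info["reference_channel"] = ref_name
    info["measured_channel"] = measured_channel
    return junctional_intensity(meas_proj, mask, info, frame=frame)
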