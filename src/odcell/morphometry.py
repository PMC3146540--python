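"""Cell and bead morphometry from fluorescence images.

Segments bright objects from a single-channel image, measures per-object
length and width as extents along the object's principal axes, and computes
single-cell volumes with the capped-cylinder (spherocylinder) model
``V = π·w²·(l − w/3)/4``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "CellMeasurement",
    "PopulationSummary",
    "SegmentationParams",
    "capped_cylinder_volume",
    "segment_and_measure",
    "measure_bead_diameters",
    "summarize_population",
]

logger = logging.getLogger(__name__)

#: minimum population size for a summary unless explicitly overridden
DEFAULT_MIN_CELLS = 200

#: fixed population-average cell width used for volume computation, µm
FIXED_WIDTH_UM = 1.26


def capped_cylinder_volume(length_um, width_um):
    """Volume of a rod modelled as a cylinder capped by two half-spheres.

    ``V = π·w²·(l − w/3)/4`` with ``l`` the total length (caps included) and
    ``w`` the width, both in µm; the result is in fl (= µm³).  ``l == w``
    degenerates to a sphere of diameter ``w``.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any input is non-positive or ``l < w`` (the model assumes a rod
        at least as long as it is wide).
    """
    l = np.asarray(length_um, dtype=float)
    w = np.asarray(width_um, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("length and width must be strictly positive")
    if np.any(l < w):
        raise ValueError(
            "length < width: the capped-cylinder model requires l >= w"
        )
    v = np.pi * w ** 2 * (l - w / 3.0) / 4.0
    return float(v) if np.isscalar(length_um) and np.isscalar(width_um) else v


@dataclass(frozen=True)
class CellMeasurement:
    """Length/width of one segmented object, with pixel provenance."""

    object_id: int
    length_um: float
    width_um: float
    centroid_px: tuple
    area_px: int = 0
    source: str = ""

    def __post_init__(self):
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("measurement must satisfy length >= width > 0")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for :func:`segment_and_measure`."""

    threshold: Optional[float] = None  # None -> Otsu
    min_area_px: int = 20
    exclude_border: bool = True
    saturation_frac: float = 0.001  # more saturated pixels than this -> error


def _principal_extents(coords: np.ndarray) -> tuple:
    """Extents of a pixel-coordinate cloud along its principal axes, in px.

    Returns (major, minor) extents.  One pixel is added to each extent to
    account for the finite pixel footprint (coordinates address centres).
    """
    centred = coords - coords.mean(axis=0)
    # eigenvectors of the 2x2 scatter matrix = principal axes
    cov = centred.T @ centred / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    proj = centred @ evecs  # column 1 is the major axis (eigh sorts ascending)
    minor = float(proj[:, 0].max() - proj[:, 0].min()) + 1.0
    major = float(proj[:, 1].max() - proj[:, 1].min()) + 1.0
    return max(major, minor), min(major, minor)


def segment_and_measure(
    image: np.ndarray,
    pixel_um: float,
    params: Optional[SegmentationParams] = None,
    source: str = "",
) -> list:
    """Segment bright objects and measure their principal-axis dimensions.

    Thresholds the image (Otsu unless a fixed threshold is given), labels
    connected components, discards undersized and border-touching objects,
    and measures each remaining object's length and width as the extents of
    its pixel cloud along the principal axes, converted to µm.

    An all-background image yields an empty list; a constant or heavily
    saturated image raises ``ValueError``.
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    if img.max() == img.min():
        raise ValueError("constant image: nothing to segment")
    if np.issubdtype(img.dtype, np.integer):
        full_scale = np.iinfo(img.dtype).max
        if np.mean(img == full_scale) > params.saturation_frac:
            raise ValueError("saturated image: too many full-scale pixels")

    thr = params.threshold
    if thr is None:
        thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        return []

    labels = sk_label(fg)
    h, w = labels.shape
    out = []
    n_border = 0
    for region in regionprops(labels):
        minr, minc, maxr, maxc = region.bbox
        if params.exclude_border and (
            minr == 0 or minc == 0 or maxr == h or maxc == w
        ):
            n_border += 1
            continue
        if region.area < params.min_area_px:
            continue
        major_px, minor_px = _principal_extents(
            region.coords.astype(float)
        )
        out.append(CellMeasurement(
            object_id=int(region.label),
            length_um=major_px * pixel_um,
            width_um=minor_px * pixel_um,
            centroid_px=tuple(float(c) for c in region.centroid),
            area_px=int(region.area),
            source=source,
        ))
    if n_border:
        logger.info("discarded %d border-touching object(s)", n_border)
    return out


def measure_bead_diameters(
    image: np.ndarray,
    pixel_um: float,
    params: Optional[SegmentationParams] = None,
) -> np.ndarray:
    """Per-bead diameters (µm) from an image of spherical beads.

    Beads are segmented like cells; the diameter of each is the mean of its
    major and minor principal-axis extents.
    """
    ms = segment_and_measure(image, pixel_um, params=params, source="beads")
    return np.array([(m.length_um + m.width_um) / 2.0 for m in ms])


@dataclass(frozen=True)
class PopulationSummary:
    n_cells: int
    length_mean_um: float
    length_sd_um: float
    width_mean_um: float
    width_sd_um: float
    volume_mean_fl: float
    volume_sd_fl: float
    width_policy: str


def summarize_population(
    measurements: Sequence[CellMeasurement],
    width_policy: str = "fixed_mean_width",
    fixed_width_um: float = FIXED_WIDTH_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
    allow_below_min: bool = False,
) -> PopulationSummary:
    """Population means/SDs of length, width and single-cell volume.

    ``width_policy`` selects the width used in the volume model:
    ``"fixed_mean_width"`` uses ``fixed_width_um`` for every cell (cells
    shorter than the fixed width fall back to spheres of their own length);
    ``"per_cell_width"`` uses each cell's measured width.

    At least ``min_cells`` measurements are required unless
    ``allow_below_min`` is set (the override is logged).  SDs are sample
    standard deviations; a single measurement reports SD 0 by convention.
    """
    n = len(measurements)
    if n == 0:
        raise ValueError("no measurements to summarise")
    if n < min_cells:
        if not allow_below_min:
            raise ValueError(
                f"only {n} cells measured; at least {min_cells} are required "
                "per the population-summary rule (pass allow_below_min=True "
                "to override)"
            )
        logger.warning("summarising only %d cells (< %d rule overridden)",
                       n, min_cells)

    lengths = np.array([m.length_um for m in measurements])
    widths = np.array([m.width_um for m in measurements])
    if width_policy == "fixed_mean_width":
        w_eff = np.minimum(fixed_width_um, lengths)  # sphere fallback
        volumes = np.pi * w_eff ** 2 * (lengths - w_eff / 3.0) / 4.0
    elif width_policy == "per_cell_width":
        volumes = np.pi * widths ** 2 * (lengths - widths / 3.0) / 4.0
    else:
        raise ValueError(f"unknown width_policy {width_policy!r}")

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    return PopulationSummary(
        n_cells=n,
        length_mean_um=float(lengths.mean()),
        length_sd_um=_sd(lengths),
        width_mean_um=float(widths.mean()),
        width_sd_um=_sd(widths),
        volume_mean_fl=float(volumes.mean()),
        volume_sd_fl=_sd(volumes),
        width_policy=width_policy,
    )
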