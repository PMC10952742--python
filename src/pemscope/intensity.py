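"""ROI intensity quantification around pericytes.

Mirrors the marker-coverage protocol used for aquaporin-4 (AQP4): select
the focal planes in which a pericyte soma is in focus, z-project them
(max projection for tracing, sum-slices for quantification), subtract a
rolling-ball background (radius 50 px), expand the traced soma outline by
0.25 μm, and take the mean gray value within the expanded ROI.  Per-group
means are then compared between pericytes with and without an adjacent PEM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely import contains_xy
from shapely.geometry import Polygon
from skimage.restoration import rolling_ball

logger = logging.getLogger("pemscope.intensity")


@dataclass
class IntensityConfig:
    n_planes: int = 8
    projection: str = "sum"           # quantification projection
    background_radius_px: int = 50
    roi_expansion_um: float = 0.25
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.background_radius_px <= 0:
            raise ValueError("background_radius_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.projection not in ("sum", "max"):
            raise ValueError("projection must be 'sum' or 'max'")


def project_planes(stack: np.ndarray, plane_indices, mode: str = "sum"
                   ) -> np.ndarray:
    """Per-pixel max or sum over the selected planes."""
    plane_indices = list(plane_indices)
    if not plane_indices:
        raise ValueError("plane_indices must be non-empty")
    stack = np.asarray(stack, dtype=float)
    if min(plane_indices) < 0 or max(plane_indices) >= stack.shape[0]:
        raise IndexError("plane index outside stack depth")
    sel = stack[plane_indices]
    if mode == "sum":
        return sel.sum(axis=0)
    if mode == "max":
        return sel.max(axis=0)
    raise ValueError("mode must be 'sum' or 'max'")


def subtract_background(image: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction; output clipped to be
    non-negative.

    For large radii the classic shrink acceleration is used: the image is
    reduced with a minimum filter, the ball is rolled on the small image,
    and the background is upsampled bilinearly — the standard approach for
    large-radius rolling-ball backgrounds.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    image = np.asarray(image, dtype=float)
    factor = max(1, int(radius_px) // 12)
    if factor == 1 or min(image.shape) < 4 * factor:
        background = rolling_ball(image, radius=radius_px)
    else:
        from scipy.ndimage import minimum_filter
        from skimage.transform import resize
        small = minimum_filter(image, size=factor)[::factor, ::factor]
        bg_small = rolling_ball(small, radius=max(1, radius_px // factor))
        background = resize(bg_small, image.shape, order=1, mode="edge",
                            anti_aliasing=False)
    return np.clip(image - background, 0.0, None)


def roi_mask(shape, polygon_um, expansion_um: float,
             pixel_size_um: float) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon after
    outward Euclidean expansion.  Polygon vertices are in μm; pixel (i, j)
    has its center at ((j + 0.5) px, (i + 0.5) px)."""
    poly = polygon_um if isinstance(polygon_um, Polygon) \
        else Polygon(np.asarray(polygon_um, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate ROI polygon")
    if expansion_um:
        poly = poly.buffer(expansion_um)
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    j0 = max(int(minx / pixel_size_um) - 1, 0)
    j1 = min(int(maxx / pixel_size_um) + 2, w)
    i0 = max(int(miny / pixel_size_um) - 1, 0)
    i1 = min(int(maxy / pixel_size_um) + 2, h)
    mask = np.zeros(shape, dtype=bool)
    if j1 <= j0 or i1 <= i0:
        return mask
    xs = (np.arange(j0, j1) + 0.5) * pixel_size_um
    ys = (np.arange(i0, i1) + 0.5) * pixel_size_um
    gx, gy = np.meshgrid(xs, ys)
    mask[i0:i1, j0:j1] = contains_xy(poly, gx, gy)
    return mask


def roi_mean_intensity(image: np.ndarray, polygon_um,
                       expansion_um: float = 0.25,
                       pixel_size_um: float = 0.5) -> float:
    """Mean gray value over pixels whose centers fall in the expanded ROI."""
    image = np.asarray(image, dtype=float)
    mask = roi_mask(image.shape, polygon_um, expansion_um, pixel_size_um)
    if not mask.any():
        return float("nan")
    return float(image[mask].mean())


def measure_pericyte_intensities(stack: np.ndarray, outlines: dict,
                                 config: IntensityConfig | None = None,
                                 plane_indices=None) -> pd.DataFrame:
    """Full quantification flow for one stack: project the selected planes
    with sum-slices, subtract the rolling-ball background, then measure the
    mean intensity in each pericyte's expanded outline."""
    config = config or IntensityConfig()
    if plane_indices is None:
        plane_indices = range(min(config.n_planes, stack.shape[0]))
    projected = project_planes(stack, plane_indices, config.projection)
    cleaned = subtract_background(projected, config.background_radius_px)
    rows = []
    for cid, poly in sorted(outlines.items()):
        rows.append(dict(cell_id=int(cid), mean_intensity=roi_mean_intensity(
            cleaned, poly, config.roi_expansion_um, config.pixel_size_um)))
    return pd.DataFrame(rows, columns=["cell_id", "mean_intensity"])


def compare_by_pem_status(per_pericyte: pd.DataFrame) -> dict:
    """Compare ROI mean intensities between pericytes with and without a
    PEM.

    ``per_pericyte`` needs columns ``mean_intensity``, ``has_pem`` and
    ``scene_id``.  Per scene the two group means are formed; scenes lacking
    either group are dropped (logged).  The across-scene paired comparison
    is a paired parametric t-test (scipy.stats.ttest_rel).
    """
    rows = []
    for scene_id, grp in per_pericyte.groupby("scene_id"):
        with_pem = grp[grp.has_pem.astype(bool)]
        without = grp[~grp.has_pem.astype(bool)]
        if not len(with_pem) or not len(without):
            logger.info("scene %s lacks one PEM-status group, dropped from "
                        "paired comparison", scene_id)
            continue
        rows.append(dict(scene_id=scene_id,
                         mean_with_pem=float(with_pem.mean_intensity.mean()),
                         mean_without_pem=float(without.mean_intensity.mean())))
    table = pd.DataFrame(rows, columns=["scene_id", "mean_with_pem",
                                        "mean_without_pem"])
    table["difference"] = table.mean_with_pem - table.mean_without_pem
    out = {"table": table,
           "mean_difference": float(table.difference.mean())
           if len(table) else None,
           "paired_t_p": None}
    if len(table) >= 2 and table.difference.std(ddof=1) > 0:
        out["paired_t_p"] = float(stats.ttest_rel(
            table.mean_with_pem, table.mean_without_pem).pvalue)
    return out
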