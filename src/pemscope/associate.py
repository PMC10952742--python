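"""CAM / PEM classification and counting protocols.

A microglia is a capillary-associated microglia (CAM) if its reference
center (nucleus center in fixed-tissue mode, soma center in in-vivo mode)
lies strictly within ``r_assoc`` (default 10 μm) of the centerline of an
eligible vessel — one whose local diameter is below ``d_vessel_max``
(default 10 μm).  It is a pericyte-associated microglia (PEM) if that
center lies strictly within ``r_assoc`` of the nucleus center of a pericyte
residing on an eligible vessel.  The two labels are independent: a PEM need
not be a CAM and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DimensionalityError, NoEligibleVesselError
from .network import VesselNetwork
from .synthdata import MICROGLIA, PERICYTE

logger = logging.getLogger("pemscope.associate")


@dataclass
class AssociationCriteria:
    r_assoc: float = 10.0
    d_vessel_max: float = 10.0
    strict_inequality: bool = True
    use_nucleus_center: bool = True   # fixed tissue; False = in-vivo soma mode

    def __post_init__(self) -> None:
        if self.r_assoc <= 0 or self.d_vessel_max <= 0:
            raise ValueError("r_assoc and d_vessel_max must be positive")

    def within(self, distance) -> np.ndarray | bool:
        if self.strict_inequality:
            return distance < self.r_assoc
        return distance <= self.r_assoc


@dataclass
class AssociationResult:
    """Labeled cell table plus the summary proportions."""

    cells: pd.DataFrame
    summary: dict = field(default_factory=dict)


def reference_coords(cells: pd.DataFrame,
                     criteria: AssociationCriteria) -> np.ndarray:
    """Cell reference centers as (n, 2) or (n, 3); raises
    :class:`DimensionalityError` if 2-D and 3-D records are mixed."""
    cols = ["x_um", "y_um", "z_um"] if criteria.use_nucleus_center \
        else ["soma_x_um", "soma_y_um", "soma_z_um"]
    xyz = cells[cols].to_numpy(dtype=float)
    z_missing = np.isnan(xyz[:, 2])
    if z_missing.all():
        return xyz[:, :2]
    if z_missing.any():
        raise DimensionalityError("table mixes 2-D and 3-D coordinates")
    return xyz


def nearest_vessel_distance(cell, network: VesselNetwork,
                            criteria: AssociationCriteria | None = None
                            ) -> float:
    """Distance (μm) from one cell's reference center to the nearest
    eligible (< d_vessel_max local diameter) centerline point; exact for
    piecewise-linear centerlines.  Raises :class:`NoEligibleVesselError`
    when no centerline location is eligible."""
    criteria = criteria or AssociationCriteria()
    if isinstance(cell, pd.Series):
        cell = reference_coords(cell.to_frame().T, criteria)[0]
    q = np.atleast_2d(np.asarray(cell, dtype=float))
    res = network.nearest_points(q, max_diameter=criteria.d_vessel_max)
    d = float(res["distance"][0])
    if not np.isfinite(d):
        raise NoEligibleVesselError(
            f"no vessel with local diameter < {criteria.d_vessel_max} μm")
    return d


def classify_cam(cells: pd.DataFrame, network: VesselNetwork,
                 criteria: AssociationCriteria | None = None) -> pd.DataFrame:
    """Add ``nearest_vessel_distance_um`` and ``is_cam`` columns (microglia
    only; other rows get is_cam = False)."""
    criteria = criteria or AssociationCriteria()
    out = cells.copy()
    out["nearest_vessel_distance_um"] = np.nan
    out["is_cam"] = False
    micro = out.cell_type == MICROGLIA
    if micro.any():
        coords = reference_coords(out.loc[micro], criteria)
        res = network.nearest_points(coords, max_diameter=criteria.d_vessel_max)
        d = res["distance"]
        out.loc[micro, "nearest_vessel_distance_um"] = np.where(
            np.isfinite(d), d, np.nan)
        out.loc[micro, "is_cam"] = np.isfinite(d) & criteria.within(d)
    return out


def _eligible_pericytes(cells: pd.DataFrame, criteria: AssociationCriteria,
                        network: VesselNetwork | None) -> pd.Series:
    """Pericytes qualify only when their host vessel's local diameter is
    below d_vessel_max; taken from the table's ``local_diameter_um`` column
    when present, else measured by snapping to the network centerline."""
    peri = cells.cell_type == PERICYTE
    eligible = pd.Series(False, index=cells.index)
    if not peri.any():
        return eligible
    if "local_diameter_um" in cells and \
            cells.loc[peri, "local_diameter_um"].notna().all():
        diam = cells.loc[peri, "local_diameter_um"].to_numpy(dtype=float)
    elif network is not None:
        coords = reference_coords(cells.loc[peri], criteria)
        diam = network.nearest_points(coords)["diameter"]
    else:
        raise ValueError("pericyte eligibility needs a local_diameter_um "
                         "column or a vessel network")
    eligible.loc[peri] = diam < criteria.d_vessel_max
    return eligible


def classify_pem(cells: pd.DataFrame,
                 criteria: AssociationCriteria | None = None,
                 network: VesselNetwork | None = None) -> pd.DataFrame:
    """Add ``nearest_pericyte_distance_um``, ``nearest_pericyte_id`` and
    ``is_pem`` to microglia rows and ``has_pem`` to pericyte rows.

    Only pericytes on eligible vessels participate.  Ties between
    equidistant pericytes are broken toward the lowest cell_id.  With zero
    (eligible) pericytes every is_pem is False.
    """
    criteria = criteria or AssociationCriteria()
    out = cells.copy()
    out["nearest_pericyte_distance_um"] = np.nan
    out["nearest_pericyte_id"] = np.nan
    out["is_pem"] = False
    out["has_pem"] = False

    micro = out.cell_type == MICROGLIA
    eligible = _eligible_pericytes(out, criteria, network)
    if not micro.any() or not eligible.any():
        return out

    m_xy = reference_coords(out.loc[micro], criteria)
    p_xy = reference_coords(out.loc[eligible], criteria)
    if m_xy.shape[1] != p_xy.shape[1]:
        raise DimensionalityError("microglia and pericytes differ in "
                                  "dimensionality")
    p_ids = out.loc[eligible, "cell_id"].to_numpy()

    tree = cKDTree(p_xy)
    k = min(4, len(p_xy))
    dist, idx = tree.query(m_xy, k=k)
    dist = np.atleast_2d(dist.T).T if k == 1 else dist
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    # tie-break equidistant pericytes toward the lowest cell_id
    best_d = dist[:, 0]
    best_id = np.empty(len(m_xy))
    for i in range(len(m_xy)):
        tied = np.abs(dist[i] - best_d[i]) <= 1e-12
        best_id[i] = np.min(p_ids[idx[i][tied]])
    is_pem = criteria.within(best_d)

    out.loc[micro, "nearest_pericyte_distance_um"] = best_d
    out.loc[micro, "nearest_pericyte_id"] = best_id
    out.loc[micro, "is_pem"] = is_pem
    partnered = set(best_id[is_pem].astype(int))
    out.loc[eligible, "has_pem"] = out.loc[eligible, "cell_id"].isin(partnered)
    return out


def classify(cells: pd.DataFrame, network: VesselNetwork,
             criteria: AssociationCriteria | None = None) -> AssociationResult:
    """Full CAM + PEM labeling with summary proportions."""
    criteria = criteria or AssociationCriteria()
    labeled = classify_pem(classify_cam(cells, network, criteria),
                           criteria, network)
    return AssociationResult(cells=labeled, summary=summarize(labeled))


def summarize(labeled: pd.DataFrame) -> dict:
    """Summary proportions; denominators of zero yield NaN, never 0."""
    micro = labeled[labeled.cell_type == MICROGLIA]
    peri = labeled[labeled.cell_type == PERICYTE]
    n_m, n_p = len(micro), len(peri)
    n_cam = int(micro.get("is_cam", pd.Series(dtype=bool)).sum())
    n_pem = int(micro.get("is_pem", pd.Series(dtype=bool)).sum())
    n_cam_pem = int((micro.get("is_cam", False) &
                     micro.get("is_pem", False)).sum()) if n_m else 0
    n_peri_pem = int(peri.get("has_pem", pd.Series(dtype=bool)).sum())

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    return {
        "n_microglia": n_m, "n_pericytes": n_p,
        "n_cam": n_cam, "n_pem": n_pem, "n_cam_and_pem": n_cam_pem,
        "n_pericytes_with_pem": n_peri_pem,
        "pct_cam": pct(n_cam, n_m),
        "pct_pem": pct(n_pem, n_m),
        "pct_cam_that_are_pem": pct(n_cam_pem, n_cam),
        "pct_pericytes_with_pem": pct(n_peri_pem, n_p),
    }


# ---------------------------------------------------------------------------
# counting protocols


#: protocol parameters: tile size (μm), sampling stride, max tiles
_PROTOCOLS = {
    "A": dict(box=(800.0, 600.0)),
    "B": dict(tile=400.0, stride=2, max_tiles=6),
    "C": dict(tile=500.0, stride=4, max_tiles=20, shrink=50.0),
}

_COUNT_COLS = {"n_microglia": ("cell_type", MICROGLIA),
               "n_pericytes": ("cell_type", PERICYTE),
               "n_cam": ("is_cam", True), "n_pem": ("is_pem", True),
               "n_pericytes_with_pem": ("has_pem", True)}


def _counts(sub: pd.DataFrame) -> dict:
    out = {}
    for name, (col, val) in _COUNT_COLS.items():
        out[name] = int((sub[col] == val).sum()) if col in sub else 0
    return out


def count_protocol(cells: pd.DataFrame, protocol: str, geometry,
                   nucleus_radius: float = 3.0,
                   mask_polygons: tuple = (),
                   max_tiles: int | None = None) -> pd.DataFrame:
    """Count cells per sampling unit under one of three ROI protocols.

    Protocol ``A``: a single 800x600 μm box placed at ``geometry`` (its
    lower corner, an (x, y) pair); cells whose nucleus disc (radius
    ``nucleus_radius``) touches any box edge are excluded.

    Protocol ``B``: ``geometry`` is a region polygon (shapely Polygon or a
    coordinate sequence); a 400x400 μm grid is laid over it, complete tiles
    are sampled with stride 2 up to 6 tiles.  Protocol ``C``: the polygon
    is first shrunk by 50 μm, then a 500x500 μm grid with stride 4 up to 20
    tiles.  For both grids a cell belongs to the tile whose half-open
    extent [x0, x1) x [y0, y1) contains its nucleus center, so a cell on a
    shared margin is counted once, in the tile whose top/left edge it
    touches.  Tiles intersecting ``mask_polygons`` (artifacts) are skipped.
    """
    from shapely.geometry import Polygon, box as shapely_box

    protocol = protocol.upper()
    if protocol not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    params = _PROTOCOLS[protocol]
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)

    if protocol == "A":
        x0, y0 = geometry
        w, h = params["box"]
        r = nucleus_radius
        inside = ((xy[:, 0] > x0 + r) & (xy[:, 0] < x0 + w - r) &
                  (xy[:, 1] > y0 + r) & (xy[:, 1] < y0 + h - r))
        row = dict(tile_index=0, x0=x0, y0=y0, width=w, height=h,
                   **_counts(cells.loc[inside]))
        return pd.DataFrame([row])

    poly = geometry if isinstance(geometry, Polygon) else Polygon(geometry)
    if "shrink" in params:
        poly = poly.buffer(-params["shrink"])
    tile = params["tile"]
    stride = params["stride"]
    limit = max_tiles if max_tiles is not None else params["max_tiles"]

    minx, miny, maxx, maxy = poly.bounds
    if poly.is_empty or maxx - minx < tile or maxy - miny < tile:
        logger.warning("protocol %s: region smaller than one %g μm tile",
                       protocol, tile)
        return pd.DataFrame(columns=["tile_index", "x0", "y0", "width",
                                     "height", *_COUNT_COLS])

    complete = []
    ny = int(np.floor((maxy - miny) / tile))
    nx = int(np.floor((maxx - minx) / tile))
    for iy in range(ny):
        for ix in range(nx):
            tx0, ty0 = minx + ix * tile, miny + iy * tile
            t = shapely_box(tx0, ty0, tx0 + tile, ty0 + tile)
            if not poly.contains(t):
                continue
            if any(t.intersects(m if isinstance(m, Polygon) else Polygon(m))
                   for m in mask_polygons):
                logger.info("protocol %s: tile at (%g, %g) skipped (artifact)",
                            protocol, tx0, ty0)
                continue
            complete.append((tx0, ty0))
    selected = complete[::stride][:limit]

    rows = []
    for k, (tx0, ty0) in enumerate(selected):
        member = ((xy[:, 0] >= tx0) & (xy[:, 0] < tx0 + tile) &
                  (xy[:, 1] >= ty0) & (xy[:, 1] < ty0 + tile))
        rows.append(dict(tile_index=k, x0=tx0, y0=ty0, width=tile,
                         height=tile, **_counts(cells.loc[member])))
    return pd.DataFrame(rows, columns=["tile_index", "x0", "y0", "width",
                                       "height", *_COUNT_COLS])
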