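"""Synthetic microvascular scenes.

Generates branching vascular trees (penetrating arteriole, order 0, through
capillary orders 1-7, to an ascending venule, order 8), places pericytes on
capillary walls and microglia as a configurable mixture of uniform,
vessel-attracted and pericyte-attracted populations, simulates longitudinal
imaging time series with configurable pericyte-associated-microglia (PEM)
retention and gain rates, and renders simple fluorescence-like intensity
stacks.  Every downstream analysis stage is exercised against these scenes.

Default parameters are calibrated so that a default scene reproduces the
prevalence regime reported for mouse somatosensory cortex: roughly 40% of
microglia capillary-associated (CAM), ~7% pericyte-associated (PEM), with a
chance-association level near 1.5%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleDensityError, InfeasibleGeometryError
from .network import ARTERIOLE, CAPILLARY, VENULE, Segment, VesselNetwork

MICROGLIA = "microglia"
PERICYTE = "pericyte"

#: canonical cell-table columns
CELL_COLUMNS = [
    "cell_id", "cell_type", "x_um", "y_um", "z_um",
    "soma_x_um", "soma_y_um", "soma_z_um", "has_nucleus", "day",
    "truth_class", "partner_id", "segment_id", "arclength_um",
    "local_diameter_um",
]


@dataclass
class WidthProfile:
    """Baseline vessel diameters per branch order and local dilation factors.

    ``baseline`` maps branch order to diameter in μm; orders not listed use
    ``capillary_baseline``.  Dilation factors are multiplicative bumps
    applied to the centerline diameter within ``bump_half_width_um`` of a
    cell landmark: 1.16 beneath a lone pericyte (P), 1.15 beneath a lone
    capillary-associated microglia (CAM) and 1.21 beneath a pericyte with an
    adjacent PEM.  ``gain_factor``/``loss_factor`` are applied to the local
    profile when a pericyte gains (x1.195) or loses (x0.91) a PEM during a
    time series.
    """

    capillary_baseline: float = 4.21
    arteriole_baseline: float = 15.0
    venule_baseline: float = 12.0
    baseline: dict = field(default_factory=dict)
    dilation: dict = field(default_factory=lambda: {
        "P": 1.16, "CAM": 1.15, "PEM": 1.21})
    gain_factor: float = 1.195
    loss_factor: float = 0.91
    bump_half_width_um: float = 6.0
    diameter_jitter_sd: float = 0.05

    def baseline_for(self, order: int) -> float:
        if order in self.baseline:
            return float(self.baseline[order])
        if order == 0:
            return self.arteriole_baseline
        if order >= 8:
            return self.venule_baseline
        return self.capillary_baseline


@dataclass
class GeneratorConfig:
    """Study conditions for scene generation.

    Densities are chosen so a default 800x600x60 μm slab yields ~95
    microglia and ~23 pericytes after projection (2-D densities
    ~2.0e-4 μm^-2 and ~4.8e-5 μm^-2), putting the analytic chance-PEM level
    near 1.5%.  ``frac_pericyte_attracted`` = 0.065 then brings the observed
    PEM proportion to ~7%, and ``frac_vessel_attracted`` = 0.30 brings CAM
    to ~40%.  Per-visit retention defaults reproduce cumulative day-0 PEM
    retention of 81% / 78% / 44% on imaging days 4 / 7 / 28.
    """

    roi_extent: tuple = (800.0, 600.0, 60.0)
    pericyte_linear_density: float = 0.012   # pericytes per μm centerline
    microglia_density: float = 3.4e-6        # per μm^3 (3-D scenes)
    frac_vessel_attracted: float = 0.30
    frac_pericyte_attracted: float = 0.065
    attraction_radius: float = 8.0
    pericyte_min_spacing: float = 25.0
    segment_length_range: tuple = (50.0, 90.0)
    branch_prob: float = 0.45
    step_um: float = 2.0
    width_profile: WidthProfile = field(default_factory=WidthProfile)
    retention_per_visit: tuple = (0.81, 78.0 / 81.0, 44.0 / 78.0)
    gain_rate: float = 0.08                  # expected new PEM per PEM-free pericyte per visit
    stable_jitter_sd: float = 3.0
    loss_jitter_sd: float = 15.0
    r_assoc: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.roi_extent):
            raise ValueError("roi_extent must be strictly positive")
        if self.pericyte_linear_density < 0 or self.microglia_density < 0:
            raise ValueError("densities must be >= 0")
        for f in (self.frac_vessel_attracted, self.frac_pericyte_attracted):
            if not 0.0 <= f <= 1.0:
                raise ValueError("attraction fractions must be in [0, 1]")
        if self.frac_vessel_attracted + self.frac_pericyte_attracted > 1.0:
            raise ValueError("attraction fractions must sum to <= 1")
        if self.attraction_radius >= self.r_assoc:
            raise ValueError("attraction_radius must be < r_assoc to "
                             "guarantee classification of attracted cells")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    def retention_for_visit(self, visit: int) -> float:
        r = self.retention_per_visit
        if np.isscalar(r):
            return float(r)
        return float(r[min(visit, len(r) - 1)])


def invivo_config(**kw) -> GeneratorConfig:
    """Preset mimicking the two-photon field of view (210x210x130 μm)."""
    kw.setdefault("roi_extent", (210.0, 210.0, 130.0))
    kw.setdefault("segment_length_range", (30.0, 55.0))
    return GeneratorConfig(**kw)


def tracking_config(**kw) -> GeneratorConfig:
    """Preset for longitudinal tracking: enough pericyte-attracted microglia
    that a single scene carries a day-0 PEM cohort of ~32 cells, the cohort
    size followed in vivo."""
    kw.setdefault("roi_extent", (500.0, 500.0, 100.0))
    kw.setdefault("microglia_density", 4.0e-6)
    kw.setdefault("pericyte_linear_density", 0.013)
    kw.setdefault("frac_pericyte_attracted", 0.34)
    kw.setdefault("frac_vessel_attracted", 0.2)
    return GeneratorConfig(**kw)


@dataclass
class SyntheticScene:
    """A vascular network plus a cell table with ground-truth placement."""

    network: VesselNetwork
    cells: pd.DataFrame
    config: GeneratorConfig | None = None
    is_2d: bool = False

    def pericytes(self) -> pd.DataFrame:
        return self.cells[self.cells.cell_type == PERICYTE]

    def microglia(self) -> pd.DataFrame:
        return self.cells[self.cells.cell_type == MICROGLIA]


@dataclass
class TimeSeriesScene:
    """Registered cell tables and networks across imaging days."""

    days: list
    cells_by_day: dict
    networks_by_day: dict
    events: pd.DataFrame          # columns: day, event, pericyte_id, microglia_id
    day0_pem: list                # microglia ids that were PEM on day 0
    config: GeneratorConfig | None = None


# ---------------------------------------------------------------------------
# vessel tree growth


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _grow_polyline(start, direction, length, bounds, rng, step, z_damp=1.0):
    """March a wiggly polyline of given arclength inside the ROI box,
    reflecting the heading off the walls."""
    margin = 1.0
    lo = np.full(3, margin)
    hi = np.asarray(bounds, dtype=float) - margin
    d = _unit(np.asarray(direction, dtype=float))
    pts = [np.asarray(start, dtype=float)]
    travelled = 0.0
    while travelled < length:
        h = min(step, length - travelled)
        d = d + rng.normal(0.0, 0.12, size=3)
        d[2] *= z_damp
        d = _unit(d)
        nxt = pts[-1] + d * h
        for k in range(3):
            if nxt[k] < lo[k] or nxt[k] > hi[k]:
                d[k] = -d[k]
                nxt = pts[-1] + d * h
        nxt = np.clip(nxt, lo, hi)
        pts.append(nxt)
        travelled += h
    return np.asarray(pts)


def _branch_directions(parent_dir, rng):
    d1 = _unit(parent_dir + rng.normal(0.0, 0.7, size=3))
    d2 = _unit(parent_dir + rng.normal(0.0, 0.7, size=3))
    if np.dot(d1, d2) > 0.9:  # keep daughters visibly divergent
        d2 = _unit(d2 - 1.2 * np.dot(d1, d2) * d1)
    return d1, d2


def generate_vessel_network(config: GeneratorConfig,
                            rng: np.random.Generator | None = None
                            ) -> VesselNetwork:
    """Grow a connected tree: one order-0 penetrating arteriole descending
    into the ROI, bifurcating through capillary orders 1-7 along a
    guaranteed main path, terminating on an order-8 ascending venule;
    side branches form capillary subtrees.  Raises
    :class:`InfeasibleGeometryError` if the ROI cannot hold a
    root-to-venule path.
    """
    if rng is None:
        rng = config.rng()
    ex, ey, ez = config.roi_extent
    if min(ex, ey) < 6 * config.step_um or ez < 5 * config.step_um:
        raise InfeasibleGeometryError(
            f"ROI {config.roi_extent} too small for an arteriole-to-venule tree")

    wp = config.width_profile
    bounds = (ex, ey, ez)
    net = VesselNetwork()
    node_counter = iter(range(10 ** 6))
    seg_counter = iter(range(10 ** 6))

    def add_node(xyz):
        nid = next(node_counter)
        net.nodes[nid] = np.asarray(xyz, dtype=float)
        return nid

    def add_segment(n0, pts, order, vclass):
        base = wp.baseline_for(order)
        diam = base + rng.normal(0.0, wp.diameter_jitter_sd, size=len(pts))
        diam = np.maximum(diam, 0.25 * base)
        n1 = add_node(pts[-1])
        net.segments.append(Segment(next(seg_counter), n0, n1, pts, diam,
                                    order=order, vessel_class=vclass))
        return n1

    def cap_length():
        lo, hi = config.segment_length_range
        return rng.uniform(lo, hi)

    # order-0 penetrating arteriole: enters at the ROI surface, descends
    root_start = np.array([ex * rng.uniform(0.3, 0.7),
                           ey * rng.uniform(0.3, 0.7), 1.0])
    n0 = add_node(root_start)
    art_pts = _grow_polyline(root_start, (0, 0, 1.0),
                             max(0.4 * ez, 4 * config.step_um),
                             bounds, rng, config.step_um)
    tip = add_segment(n0, art_pts, order=0, vclass=ARTERIOLE)
    tip_dir = _unit(art_pts[-1] - art_pts[-2])

    z_damp = min(1.0, ez / min(ex, ey))  # thin slabs keep capillaries planar

    def grow_side(node, direction, order):
        """Side capillary subtree; bifurcates with branch_prob up to order 7."""
        pts = _grow_polyline(net.nodes[node], direction, cap_length(),
                             bounds, rng, config.step_um, z_damp)
        end = add_segment(node, pts, order=order, vclass=CAPILLARY)
        if order < 7 and rng.uniform() < config.branch_prob:
            d1, d2 = _branch_directions(_unit(pts[-1] - pts[-2]), rng)
            grow_side(end, d1, order + 1)
            grow_side(end, d2, order + 1)

    # main path: capillary orders 1..7, one side branch at each junction
    for order in range(1, 8):
        d_main, d_side = _branch_directions(tip_dir, rng)
        grow_side(tip, d_side, order)
        pts = _grow_polyline(net.nodes[tip], d_main, cap_length(),
                             bounds, rng, config.step_um, z_damp)
        tip = add_segment(tip, pts, order=order, vclass=CAPILLARY)
        tip_dir = _unit(pts[-1] - pts[-2])

    # order-8 ascending venule: heads back toward the surface
    ven_pts = _grow_polyline(net.nodes[tip], (0, 0, -1.0),
                             max(0.4 * ez, 4 * config.step_um),
                             bounds, rng, config.step_um)
    add_segment(tip, ven_pts, order=8, vclass=VENULE)

    net.validate()
    return net


# ---------------------------------------------------------------------------
# cell placement


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        CELL_COLUMNS,
        [int, str, float, float, float, float, float, float, bool, int,
         str, float, int, float, float])})


def _perp_unit(tangent, rng):
    t = _unit(tangent)
    v = rng.normal(size=3)
    v -= np.dot(v, t) * t
    return _unit(v)


def _ball_offset(radius, rng):
    """Uniform point in a 3-D ball of given radius."""
    while True:
        v = rng.uniform(-1, 1, size=3)
        if np.dot(v, v) <= 1.0:
            return v * radius


def place_cells(network: VesselNetwork, config: GeneratorConfig,
                rng: np.random.Generator | None = None) -> SyntheticScene:
    """Place pericytes on capillary centerlines (minimum spacing enforced)
    and microglia as the configured uniform / vessel-attracted /
    pericyte-attracted mixture; record ground-truth placement classes and
    apply the width-profile dilations at cell landmarks."""
    if rng is None:
        rng = config.rng()
    ex, ey, ez = config.roi_extent
    wp = config.width_profile
    margin = wp.bump_half_width_um + 10.0  # keep landmarks measurable:
    # clear of the branchpoint exclusion zone and side-offset sampling

    rows = []
    next_id = iter(range(10 ** 7))

    # -- pericytes
    caps = [s for s in network.capillary_segments()
            if s.length > 2 * margin + 1.0]
    usable = np.array([s.length - 2 * margin for s in caps])
    total_cap = network.total_length(CAPILLARY)
    n_peri = rng.poisson(config.pericyte_linear_density * total_cap)
    placed = []  # (segment, s, xyz)
    tries = 0
    while len(placed) < n_peri:
        tries += 1
        if tries > 500 * max(n_peri, 1) or not caps:
            raise InfeasibleDensityError(
                f"could not place {n_peri} pericytes with spacing "
                f"{config.pericyte_min_spacing} μm on {total_cap:.0f} μm of "
                "capillary")
        seg = caps[rng.choice(len(caps), p=usable / usable.sum())]
        s = rng.uniform(margin, seg.length - margin)
        # minimum spacing is arclength along the centerline, i.e. between
        # pericytes sharing a segment
        if all(p[0].segment_id != seg.segment_id or
               abs(p[1] - s) >= config.pericyte_min_spacing
               for p in placed):
            placed.append((seg, s, seg.point_at(s)))

    for seg, s, xyz in placed:
        cs = seg.arclengths
        i = int(np.searchsorted(cs, s))
        tangent = seg.points[min(i, len(seg.points) - 1)] - seg.points[max(i - 1, 0)]
        d_local = seg.diameter_at(s)
        nucleus = xyz + _perp_unit(tangent, rng) * (d_local / 2.0)
        nucleus = np.clip(nucleus, 0.0, [ex, ey, ez])
        cid = next(next_id)
        rows.append(dict(cell_id=cid, cell_type=PERICYTE,
                         x_um=nucleus[0], y_um=nucleus[1], z_um=nucleus[2],
                         soma_x_um=nucleus[0], soma_y_um=nucleus[1],
                         soma_z_um=nucleus[2], has_nucleus=True, day=0,
                         truth_class="", partner_id=np.nan,
                         segment_id=seg.segment_id, arclength_um=s,
                         local_diameter_um=d_local))
    peri_rows = list(rows)
    peri_pos = np.array([[r["x_um"], r["y_um"], r["z_um"]] for r in peri_rows]
                        ) if peri_rows else np.empty((0, 3))

    # -- microglia
    n_micro = rng.poisson(config.microglia_density * ex * ey * ez)
    pu = 1.0 - config.frac_vessel_attracted - config.frac_pericyte_attracted
    cap_lengths = np.array([s.length for s in network.capillary_segments()])
    for _ in range(n_micro):
        u = rng.uniform()
        if u < pu or (u >= pu + config.frac_vessel_attracted and not peri_rows):
            cls = "uniform"
            pos = rng.uniform(0, 1, size=3) * [ex, ey, ez]
            partner, seg_id, s = np.nan, -1, np.nan
        elif u < pu + config.frac_vessel_attracted:
            cls = "vessel"
            # rejection keeps vessel-attracted microglia clear of pericyte
            # neighborhoods (even in x/y projection), so PEM enrichment is
            # governed solely by frac_pericyte_attracted
            for _ in range(100):
                seg = network.capillary_segments()[rng.choice(
                    len(cap_lengths), p=cap_lengths / cap_lengths.sum())]
                s = rng.uniform(0, seg.length)
                pos = seg.point_at(s) + _ball_offset(
                    config.attraction_radius, rng)
                pos = np.clip(pos, 0.0, [ex, ey, ez])
                clear_euclid = not len(peri_pos) or np.min(np.linalg.norm(
                    peri_pos[:, :2] - pos[:2], axis=1)) \
                    > config.r_assoc + 0.25
                # also stay clear of pericyte dilation bumps along this
                # segment so lone-CAM width sites read the CAM bump only
                same_seg = [p for p in peri_rows
                            if p["segment_id"] == seg.segment_id]
                clear_arc = all(abs(p["arclength_um"] - s) >
                                2 * wp.bump_half_width_um + 2.0
                                for p in same_seg)
                if clear_euclid and clear_arc:
                    break
            partner, seg_id = np.nan, seg.segment_id
        else:
            cls = "pericyte"
            j = rng.integers(len(peri_rows))
            pos = peri_pos[j] + _ball_offset(config.attraction_radius, rng)
            pos = np.clip(pos, 0.0, [ex, ey, ez])
            partner = peri_rows[j]["cell_id"]
            seg_id, s = peri_rows[j]["segment_id"], np.nan
        cid = next(next_id)
        rows.append(dict(cell_id=cid, cell_type=MICROGLIA,
                         x_um=pos[0], y_um=pos[1], z_um=pos[2],
                         soma_x_um=pos[0], soma_y_um=pos[1], soma_z_um=pos[2],
                         has_nucleus=True, day=0, truth_class=cls,
                         partner_id=partner, segment_id=seg_id,
                         arclength_um=s, local_diameter_um=np.nan))

    cells = pd.DataFrame(rows, columns=CELL_COLUMNS) if rows else _empty_cells()
    scene = SyntheticScene(network=network, cells=cells, config=config)
    _apply_landmark_dilations(scene, rng)
    return scene


def _apply_landmark_dilations(scene: SyntheticScene, rng) -> None:
    """Widen the vessel profile beneath cell landmarks: P / PEM factors at
    pericytes (PEM if a pericyte-attracted microglia targets it), CAM factor
    at lone vessel-attracted microglia."""
    cfg = scene.config
    wp = cfg.width_profile
    cells = scene.cells
    peri = cells[cells.cell_type == PERICYTE]
    micro = cells[cells.cell_type == MICROGLIA]
    pem_targets = set(micro.loc[micro.truth_class == "pericyte",
                                "partner_id"].dropna().astype(int))

    for _, p in peri.iterrows():
        seg = scene.network.segment(int(p.segment_id))
        factor = wp.dilation["PEM"] if int(p.cell_id) in pem_targets \
            else wp.dilation["P"]
        seg.scale_diameters(p.arclength_um, factor, wp.bump_half_width_um)

    peri_pos = peri[["x_um", "y_um", "z_um"]].to_numpy()
    for _, m in micro[micro.truth_class == "vessel"].iterrows():
        pos = np.array([m.x_um, m.y_um, m.z_um])
        if len(peri_pos) and np.min(
                np.linalg.norm(peri_pos - pos, axis=1)) <= cfg.r_assoc:
            continue  # near a pericyte: not a lone-CAM landmark
        seg = scene.network.segment(int(m.segment_id))
        res = scene.network.nearest_points(pos[None, :])
        if int(res["segment_id"][0]) != seg.segment_id:
            continue
        s = float(res["arclength"][0])
        # skip if the bump would overlap a pericyte bump on this segment
        ps = peri[peri.segment_id == seg.segment_id]
        if len(ps) and np.min(np.abs(ps.arclength_um.to_numpy() - s)) \
                <= 2 * wp.bump_half_width_um:
            continue
        seg.scale_diameters(s, wp.dilation["CAM"], wp.bump_half_width_um)
    scene.network.invalidate_cache()

    # refresh pericyte local diameters after dilation
    for idx, p in peri.iterrows():
        seg = scene.network.segment(int(p.segment_id))
        cells.at[idx, "local_diameter_um"] = seg.diameter_at(p.arclength_um)


def generate_scene(config: GeneratorConfig,
                   rng: np.random.Generator | None = None) -> SyntheticScene:
    """Convenience: grow a network and place cells from one seeded stream."""
    if rng is None:
        rng = config.rng()
    return place_cells(generate_vessel_network(config, rng), config, rng)


# ---------------------------------------------------------------------------
# sectioning


def project_to_section(scene: SyntheticScene, thickness: float,
                       z_center: float) -> SyntheticScene:
    """Emulate analysis of a thin slab: keep cells whose nucleus center lies
    within the slab, drop their z, and clip vessel polylines to the slab.
    An empty slab yields an empty scene."""
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    z0, z1 = z_center - thickness / 2.0, z_center + thickness / 2.0

    cells = scene.cells[(scene.cells.z_um >= z0) &
                        (scene.cells.z_um <= z1)].copy()
    cells["z_um"] = np.nan
    cells["soma_z_um"] = np.nan

    net = VesselNetwork()
    node_counter = iter(range(10 ** 6))
    for seg in scene.network.segments:
        z = seg.points[:, 2]
        inside = (z >= z0) & (z <= z1)
        # contiguous runs of in-slab vertices become clipped sub-segments
        run_start = None
        for i in range(len(inside) + 1):
            if i < len(inside) and inside[i]:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                pts = seg.points[run_start:i]
                dm = seg.diameters[run_start:i]
                if len(pts) >= 2:
                    n0 = next(node_counter)
                    n1 = next(node_counter)
                    net.nodes[n0] = pts[0].copy()
                    net.nodes[n1] = pts[-1].copy()
                    net.segments.append(Segment(
                        len(net.segments), n0, n1, pts.copy(), dm.copy(),
                        order=seg.order, vessel_class=seg.vessel_class))
                run_start = None
    return SyntheticScene(network=net, cells=cells, config=scene.config,
                          is_2d=True)


# ---------------------------------------------------------------------------
# longitudinal time series


def simulate_timepoints(scene: SyntheticScene, days: list,
                        config: GeneratorConfig | None = None,
                        rng: np.random.Generator | None = None
                        ) -> TimeSeriesScene:
    """Simulate repeat imaging visits.

    Per visit each current PEM is retained with the per-visit retention
    probability (retained cells re-jitter within the attraction radius of
    their pericyte; lost cells walk away beyond the association radius);
    PEM-free pericytes gain a new PEM with probability ~gain_rate by
    recruiting a free microglia; all other microglia jitter in place without
    crossing the association radius, so the generator's event log is the
    exact ground truth for trackers.  Vessel diameter at a pericyte is
    scaled by the gain/loss width factor when its PEM status changes.
    """
    config = config or scene.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    days = list(days)
    if days != sorted(days) or len(set(days)) != len(days):
        raise ValueError("days must be strictly increasing")
    if days[0] != 0:
        raise ValueError("day 0 must be included")

    ex, ey, ez = config.roi_extent
    wp = config.width_profile
    r = config.r_assoc

    cells = scene.cells.copy()
    peri = cells[cells.cell_type == PERICYTE]
    peri_pos = peri[["x_um", "y_um", "z_um"]].to_numpy()
    peri_ids = peri.cell_id.to_numpy()
    peri_idx = {int(pid): k for k, pid in enumerate(peri_ids)}
    peri_loc = {int(p.cell_id): (int(p.segment_id), float(p.arclength_um))
                for _, p in peri.iterrows()}

    def min_peri_dist(pos):
        if not len(peri_pos):
            return np.inf
        return float(np.min(np.linalg.norm(peri_pos - pos, axis=1)))

    def nearest_peri(pos):
        d = np.linalg.norm(peri_pos - pos, axis=1)
        return int(peri_ids[int(np.argmin(d))]), float(np.min(d))

    def jitter_adjacent(cur, pid):
        """Small bounded walk that keeps the microglia inside the
        attraction ball of its partner pericyte (and the partner nearest),
        so retained PEM displacements stay well below the tracking bound."""
        ppos = peri_pos[peri_idx[pid]]
        for _ in range(100):
            cand = np.clip(cur + rng.normal(0.0, config.stable_jitter_sd,
                                            size=3), 0.0, [ex, ey, ez])
            if np.linalg.norm(cand - ppos) <= config.attraction_radius \
                    and nearest_peri(cand)[0] == pid:
                return cand
        return cur

    def adjacent_offset(pid):
        """Position in the attraction ball of pericyte ``pid`` for which
        that pericyte is also the nearest one (keeps partner identity
        stable when pericytes are closely spaced)."""
        ppos = peri_pos[peri_idx[pid]]
        for _ in range(100):
            cand = np.clip(ppos + _ball_offset(config.attraction_radius, rng),
                           0.0, [ex, ey, ez])
            if nearest_peri(cand)[0] == pid:
                return cand
        return np.clip(ppos + 0.01 * np.ones(3), 0.0, [ex, ey, ez])

    # initial PEM links from geometry (includes chance associations)
    links: dict[int, int] = {}
    micro = cells[cells.cell_type == MICROGLIA]
    for idx, m in micro.iterrows():
        pos = np.array([m.x_um, m.y_um, m.z_um])
        if len(peri_pos):
            pid, d = nearest_peri(pos)
            if d < r:
                links[int(m.cell_id)] = pid

    net = scene.network.copy()
    cells_by_day = {0: cells.assign(day=0)}
    networks_by_day = {0: net.copy()}
    events = []
    day0_pem = sorted(links)

    pos_of = {int(c.cell_id): np.array([c.x_um, c.y_um, c.z_um])
              for _, c in micro.iterrows()}

    def scale_at(pid, factor):
        seg_id, s = peri_loc[pid]
        net.segment(seg_id).scale_diameters(s, factor, wp.bump_half_width_um)
        net.invalidate_cache()

    for visit, day in enumerate(days[1:]):
        p_keep = config.retention_for_visit(visit)
        had_pem = set(links.values())  # start-of-visit pericyte PEM state
        # retention / loss of current PEM microglia
        departed: dict[int, int] = {}
        for mid in sorted(links):
            pid = links[mid]
            if rng.uniform() < p_keep:
                pos_of[mid] = jitter_adjacent(pos_of[mid], pid)
            else:
                for _ in range(200):
                    cand = np.clip(pos_of[mid] + rng.normal(
                        0.0, config.loss_jitter_sd, size=3), 0.0, [ex, ey, ez])
                    if min_peri_dist(cand) > r + 1.0:
                        break
                pos_of[mid] = cand
                del links[mid]
                departed.setdefault(pid, mid)
        # a pericyte loses its PEM state (and dilation) only when the last
        # adjacent microglia departs
        still_linked = set(links.values())
        for pid in sorted(departed):
            if pid not in still_linked:
                scale_at(pid, wp.loss_factor)
                events.append(dict(day=day, event="loss", pericyte_id=pid,
                                   microglia_id=departed[pid]))
        # gains only at pericytes that started the visit without a PEM
        p_gain = 1.0 - np.exp(-config.gain_rate)
        free_micro = [mid for mid in sorted(pos_of)
                      if mid not in links
                      and min_peri_dist(pos_of[mid]) > r + 1.0]
        for pid in sorted(int(i) for i in peri_ids):
            if pid in had_pem or not free_micro:
                continue
            if rng.uniform() < p_gain:
                mid = free_micro.pop(rng.integers(len(free_micro)))
                pos_of[mid] = adjacent_offset(pid)
                links[mid] = pid
                scale_at(pid, wp.gain_factor)
                events.append(dict(day=day, event="gain", pericyte_id=pid,
                                   microglia_id=mid))
        # non-PEM microglia jitter in place, never crossing r_assoc
        for mid in sorted(pos_of):
            if mid in links:
                continue
            if any(e["microglia_id"] == mid and e["day"] == day
                   for e in events):
                continue
            cur = pos_of[mid]
            was_adjacent = min_peri_dist(cur) < r
            for _ in range(50):
                cand = np.clip(cur + rng.normal(
                    0.0, config.stable_jitter_sd, size=3), 0.0, [ex, ey, ez])
                if was_adjacent or min_peri_dist(cand) > r + 0.01:
                    break
            else:
                cand = cur
            pos_of[mid] = cand

        day_cells = cells.copy()
        day_cells["day"] = day
        for idx, c in day_cells.iterrows():
            if c.cell_type == MICROGLIA:
                x, y, z = pos_of[int(c.cell_id)]
                day_cells.loc[idx, ["x_um", "y_um", "z_um",
                                    "soma_x_um", "soma_y_um", "soma_z_um"]] = \
                    [x, y, z, x, y, z]
        cells_by_day[day] = day_cells
        networks_by_day[day] = net.copy()

    ev = pd.DataFrame(events, columns=["day", "event", "pericyte_id",
                                       "microglia_id"])
    return TimeSeriesScene(days=days, cells_by_day=cells_by_day,
                           networks_by_day=networks_by_day, events=ev,
                           day0_pem=day0_pem, config=config)


# ---------------------------------------------------------------------------
# intensity stacks


@dataclass
class MarkerModel:
    """Simple fluorescence model: per-covered-pericyte Gaussian blob plus a
    smooth background field and additive read noise (arbitrary units)."""

    signal_amplitude: float = 100.0
    signal_sigma_um: float = 3.0
    covered_fraction: float = 0.5
    background_level: float = 10.0
    background_wobble: float = 0.0      # amplitude of the smooth field
    background_scale_um: float = 50.0
    noise_sd: float = 0.0
    pixel_size_um: float = 0.5
    soma_radius_um: float = 2.75


def pericyte_outlines(scene: SyntheticScene,
                      soma_radius_um: float = 2.75, n_vertices: int = 16
                      ) -> dict:
    """Circular soma outlines (μm coordinates) for each pericyte, the
    synthetic stand-in for manual tracing."""
    out = {}
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    for _, p in scene.pericytes().iterrows():
        out[int(p.cell_id)] = np.column_stack([
            p.x_um + soma_radius_um * np.cos(ang),
            p.y_um + soma_radius_um * np.sin(ang)])
    return out


def render_intensity_stack(scene: SyntheticScene, marker: MarkerModel,
                           planes: int = 8,
                           rng: np.random.Generator | None = None):
    """Render a (planes, H, W) float stack over the ROI's x/y footprint.

    Returns ``(stack, truth)`` where ``truth`` is a per-pericyte DataFrame
    with the covered flag and the mean added signal within the soma outline
    (computed here by direct pixel masking, independent of the intensity
    module)."""
    if planes < 1:
        raise ValueError("planes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(scene.config.seed + 2 if scene.config
                                    else 0)
    ex, ey = scene.config.roi_extent[:2] if scene.config else (
        scene.cells.x_um.max() + 20, scene.cells.y_um.max() + 20)
    px = marker.pixel_size_um
    w, h = int(np.ceil(ex / px)), int(np.ceil(ey / px))
    xs = (np.arange(w) + 0.5) * px
    ys = (np.arange(h) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)

    background = np.full((h, w), marker.background_level, dtype=float)
    if marker.background_wobble > 0:
        background += marker.background_wobble * np.sin(
            2 * np.pi * gx / marker.background_scale_um) * np.cos(
            2 * np.pi * gy / marker.background_scale_um)

    peri = scene.pericytes()
    covered = rng.uniform(size=len(peri)) < marker.covered_fraction
    signal = np.zeros((h, w))
    win = 4.0 * marker.signal_sigma_um
    for cov, (_, p) in zip(covered, peri.iterrows()):
        if not cov or marker.signal_amplitude == 0:
            continue
        j0 = max(int((p.x_um - win) / px), 0)
        j1 = min(int((p.x_um + win) / px) + 1, w)
        i0 = max(int((p.y_um - win) / px), 0)
        i1 = min(int((p.y_um + win) / px) + 1, h)
        r2 = (gx[i0:i1, j0:j1] - p.x_um) ** 2 + \
            (gy[i0:i1, j0:j1] - p.y_um) ** 2
        signal[i0:i1, j0:j1] += marker.signal_amplitude * np.exp(
            -r2 / (2 * marker.signal_sigma_um ** 2))

    stack = np.empty((planes, h, w))
    for k in range(planes):
        plane = background + signal
        if marker.noise_sd > 0:
            plane = plane + rng.normal(0.0, marker.noise_sd, size=(h, w))
        stack[k] = plane

    # ground truth: mean added signal (per plane) within each soma disc
    truth_rows = []
    for cov, (_, p) in zip(covered, peri.iterrows()):
        rr = marker.soma_radius_um + px
        j0 = max(int((p.x_um - rr) / px), 0)
        j1 = min(int((p.x_um + rr) / px) + 1, w)
        i0 = max(int((p.y_um - rr) / px), 0)
        i1 = min(int((p.y_um + rr) / px) + 1, h)
        mask = (gx[i0:i1, j0:j1] - p.x_um) ** 2 + \
            (gy[i0:i1, j0:j1] - p.y_um) ** 2 <= marker.soma_radius_um ** 2
        mean_sig = float(signal[i0:i1, j0:j1][mask].mean()) \
            if mask.any() else np.nan
        truth_rows.append(dict(cell_id=int(p.cell_id), covered=bool(cov),
                               mean_added_intensity=mean_sig))
    truth = pd.DataFrame(truth_rows,
                         columns=["cell_id", "covered",
                                  "mean_added_intensity"])
    return stack, truth
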